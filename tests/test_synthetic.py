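"""Generator correctness: pedigree structure, Mendelian transmission,
LD control, and the generative phenotype rules."""

import numpy as np
import pandas as pd
import pytest

from poegwas.core import FEMALE, MALE, MISSING_PARENT, PedigreeError
from poegwas.synthetic import (
    ArchitectureSpec,
    CausalVariant,
    SimulatedCohort,
    founder_pedigree,
    genetic_values,
    simulate_cohort,
    simulate_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
    trio_pedigree,
)


class TestSimulatePedigree:
    def test_smallest_pedigree_is_a_trio_family(self):
        ped = simulate_pedigree(2, 2, seed=1)
        founders = set(ped.founders())
        assert founders == {"F1", "F2"}
        children = ped.table.loc[~ped.is_founder()]
        assert len(children) >= 1
        assert (children["father"] == "F1").all()
        assert (children["mother"] == "F2").all()

    def test_single_generation_gives_founders_only(self):
        ped = simulate_pedigree(2, 1, seed=1)
        assert len(ped) == 2
        assert ped.is_founder().all()

    def test_parents_exist_and_nobody_is_own_ancestor(self):
        ped = simulate_pedigree(100, 3, mating_rate=0.8, seed=7)
        known = set(ped.table["iid"])
        named = ped.table.loc[ped.table["father"] != MISSING_PARENT, "father"]
        assert set(named) <= known
        # DFS ancestor check: no individual reachable from itself
        parent_of = {
            r.iid: [p for p in (r.father, r.mother) if p in known]
            for r in ped.table.itertuples()
        }
        for start in parent_of:
            stack = list(parent_of[start])
            seen = set()
            while stack:
                node = stack.pop()
                assert node != start, "cycle in pedigree"
                if node not in seen:
                    seen.add(node)
                    stack.extend(parent_of[node])

    def test_sexes_consistent_with_parent_roles(self):
        ped = simulate_pedigree(30, 3, seed=3)
        sex = dict(zip(ped.table["iid"], ped.table["sex"]))
        for r in ped.table.itertuples():
            if r.father != MISSING_PARENT:
                assert sex[r.father] == MALE
            if r.mother != MISSING_PARENT:
                assert sex[r.mother] == FEMALE

    def test_impossible_mating_raises(self):
        with pytest.raises(PedigreeError):
            simulate_pedigree(1, 2, seed=0)

    def test_seed_reproducibility(self):
        a = simulate_pedigree(50, 3, seed=9).table
        b = simulate_pedigree(50, 3, seed=9).table
        pd.testing.assert_frame_equal(a, b)


class TestSimulateHaplotypes:
    def test_empirical_maf_within_requested_range(self):
        ped = founder_pedigree(3000)
        geno = simulate_haplotypes(ped, 50, maf_range=(0.2, 0.4), seed=2)
        freq = geno.allele_frequency()
        maf = np.minimum(freq, 1 - freq)
        # binomial error on 6000 haplotypes: sd <= 0.0065
        assert (maf > 0.2 - 0.03).all() and (maf < 0.4 + 0.03).all()

    def test_child_paternal_allele_comes_from_father(self):
        ped = trio_pedigree(50)
        geno = simulate_haplotypes(ped, 30, seed=4)
        pos = {s: i for i, s in enumerate(geno.samples)}
        for r in ped.trios().itertuples():
            ci, fi = pos[r.iid], pos[r.father]
            child_pat = geno.paternal[ci]
            father = {tuple(geno.paternal[fi]), tuple(geno.maternal[fi])}
            # every allele matches one of the father's two at that site
            ok = (child_pat == geno.paternal[fi]) | (child_pat == geno.maternal[fi])
            assert ok.all()

    def test_block_size_one_gives_near_zero_ld(self):
        ped = founder_pedigree(1500)
        geno = simulate_haplotypes(ped, 60, ld_block_size=1, seed=6)
        add = geno.additive()
        corr = np.corrcoef(add.T)
        off = corr[np.triu_indices(60, k=1)]
        assert np.mean(off**2) < 0.01

    def test_block_structure_raises_ld(self):
        ped = founder_pedigree(1500)
        geno = simulate_haplotypes(
            ped, 60, ld_block_size=5, target_r2=0.8, seed=6
        )
        add = geno.additive()
        within = []
        for b in range(12):
            cols = add[:, 5 * b : 5 * b + 5]
            c = np.corrcoef(cols.T)
            within.extend((c[np.triu_indices(5, k=1)] ** 2).tolist())
        assert np.mean(within) > 0.5

    def test_zero_variants_gives_empty_matrix(self):
        ped = founder_pedigree(5)
        geno = simulate_haplotypes(ped, 0, seed=0)
        assert geno.n_variants == 0
        assert geno.paternal.shape == (5, 0)

    def test_seed_reproducibility(self):
        ped = founder_pedigree(100)
        a = simulate_haplotypes(ped, 20, seed=3)
        b = simulate_haplotypes(ped, 20, seed=3)
        assert np.array_equal(a.paternal, b.paternal)
        assert np.array_equal(a.maternal, b.maternal)


class TestSimulatePhenotypes:
    def test_null_model_is_standard_normal_noise(self):
        ped = founder_pedigree(5000)
        geno = simulate_haplotypes(ped, 5, seed=1)
        cohort = SimulatedCohort(ped, geno)
        spec = ArchitectureSpec(causal=(), background_h2=0.0, year_effect=0.0)
        phen = simulate_phenotypes(cohort, spec, seed=2)
        y_std = (phen["value"] - np.where(phen["sex"] == MALE, 178.8, 165.6)) / 6.6
        assert abs(y_std.mean()) < 0.05
        assert abs(y_std.std() - 1.0) < 0.05

    def test_opposing_effects_project_onto_additive_slope(self):
        # regression on unordered count recovers the mean parental effect
        ped = founder_pedigree(40000)
        spec = ArchitectureSpec(
            causal=(CausalVariant("var1", "opposing", a_p=-0.12, a_m=0.056),),
            background_h2=0.0,
        )
        cohort = simulate_cohort(
            ped, spec, 3, seed=8, frequencies=np.full(3, 0.05)
        )
        phen = cohort.phenotypes["height"]
        y = (phen["value"].to_numpy() - np.where(phen["sex"] == MALE, 178.8, 165.6)) / 6.6
        g = cohort.genotypes.additive()[:, 0]
        slope = np.polyfit(g, y, 1)[0]
        expected = (-0.12 + 0.056) / 2.0
        assert slope == pytest.approx(expected, abs=0.02)

    def test_recessive_effect_appears_only_in_minor_homozygotes(self):
        ped = founder_pedigree(50000)
        spec = ArchitectureSpec(
            causal=(CausalVariant("var1", "recessive", a_r=0.5),),
            background_h2=0.0,
        )
        cohort = simulate_cohort(
            ped, spec, 2, seed=9, frequencies=np.full(2, 0.3)
        )
        phen = cohort.phenotypes["height"]
        y = (phen["value"].to_numpy() - np.where(phen["sex"] == MALE, 178.8, 165.6)) / 6.6
        geno = cohort.genotypes
        hom = (geno.paternal[:, 0] == 1) & (geno.maternal[:, 0] == 1)
        gap = y[hom].mean() - y[~hom].mean()
        assert gap == pytest.approx(0.5, abs=0.05)

    def test_monomorphic_causal_variant_raises(self):
        ped = founder_pedigree(20)
        geno = simulate_haplotypes(ped, 2, seed=1)
        geno.paternal[:, 0] = 0.0
        geno.maternal[:, 0] = 0.0
        cohort = SimulatedCohort(ped, geno)
        spec = ArchitectureSpec(causal=(CausalVariant("var1", "additive", a=0.1),))
        with pytest.raises(ValueError, match="monomorphic"):
            simulate_phenotypes(cohort, spec, seed=0)

    def test_full_sib_phenotype_correlation_matches_background(self):
        # families of several sibs: cor(sib pairs) ~ h2/2
        ped = simulate_pedigree(1200, 2, mating_rate=1.0, seed=21, mean_children=3.0)
        geno = simulate_haplotypes(ped, 1, seed=22)
        cohort = SimulatedCohort(ped, geno)
        h2 = 0.5
        spec = ArchitectureSpec(causal=(), background_h2=h2)
        phen = simulate_phenotypes(cohort, spec, seed=23).set_index("iid")
        y = (phen["value"] - np.where(phen["sex"] == MALE, 178.8, 165.6)) / 6.6
        pairs = []
        for _, kids in ped.table.loc[~ped.is_founder()].groupby(["father", "mother"]):
            ids = list(kids["iid"])
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    pairs.append((y[ids[i]], y[ids[j]]))
        arr = np.array(pairs)
        assert len(arr) > 300
        r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
        assert r == pytest.approx(h2 / 2.0, abs=0.08)

    def test_maternal_genotype_effect_tracks_mothers_genotype(self):
        ped = trio_pedigree(20000)
        spec = ArchitectureSpec(
            causal=(
                CausalVariant("var1", "additive", a=0.0, maternal_genotype=0.3),
            ),
            background_h2=0.0,
        )
        cohort = simulate_cohort(ped, spec, 2, seed=31, frequencies=np.full(2, 0.3))
        phen = cohort.phenotypes["height"].set_index("iid")
        y = (phen["value"] - np.where(phen["sex"] == MALE, 178.8, 165.6)) / 6.6
        pos = {s: i for i, s in enumerate(cohort.genotypes.samples)}
        add = cohort.genotypes.additive()
        kids = ped.trios()
        mg = np.array([add[pos[m], 0] for m in kids["mother"]])
        yk = np.array([y[c] for c in kids["iid"]])
        slope = np.polyfit(mg, yk, 1)[0]
        # child also carries the transmitted maternal allele, but with a=0
        # only the mother's genotype drives the slope
        assert slope == pytest.approx(0.3, abs=0.03)


def test_two_trait_scaling_shares_causals():
    spec = ArchitectureSpec(
        causal=(CausalVariant("var1", "paternal", a_p=-0.12),), trait_sd=6.6
    )
    birth = spec.scaled(2.0, trait_sd=2.5, trait="birth_length")
    assert birth.causal[0].a_p == pytest.approx(-0.24)
    assert birth.trait_sd == 2.5
    assert birth.causal[0].variant_id == "var1"
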