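"""Trio origin deduction, non-transmitted-allele tests and ordered
genotype summaries."""

import numpy as np
import pandas as pd
import pytest

from poegwas.calibration import CorrectionFactor
from poegwas.imprinting import (
    assign_parental_origin,
    assign_trio_origins,
    nontransmitted_test,
    ordered_genotype_summary,
    transmission_table,
)
from poegwas.synthetic import (
    ArchitectureSpec,
    CausalVariant,
    simulate_cohort,
    trio_pedigree,
)

from conftest import standardize_quiet


class TestAssignParentalOrigin:
    def test_forced_transmission_from_homozygous_parents(self):
        assert assign_parental_origin(1, 0, 2) == (0, 1)
        assert assign_parental_origin(1, 2, 0) == (1, 0)
        assert assign_parental_origin(1, 1, 0) == (1, 0)
        assert assign_parental_origin(1, 0, 1) == (0, 1)

    def test_homozygous_child_needs_no_parents(self):
        assert assign_parental_origin(2, 1, 1) == (1, 1)
        assert assign_parental_origin(0, 1, 1) == (0, 0)

    def test_triple_heterozygote_is_ambiguous(self):
        assert assign_parental_origin(1, 1, 1) is None

    def test_mendelian_inconsistency_raises(self):
        with pytest.raises(ValueError, match="Mendelian"):
            assign_parental_origin(2, 0, 1)
        with pytest.raises(ValueError, match="Mendelian"):
            assign_parental_origin(1, 0, 0)

    def test_allele_pair_input_accepted(self):
        assert assign_parental_origin((0, 1), (0, 0), (1, 1)) == (0, 1)


class TestAssignTrioOrigins:
    def test_agrees_with_simulator_truth_on_unambiguous_trios(self):
        ped = trio_pedigree(400)
        cohort = simulate_cohort(
            ped, ArchitectureSpec(causal=()), 20, maf_range=(0.2, 0.5), seed=51
        )
        geno = cohort.genotypes
        add = np.round(geno.additive())
        pat, mat = assign_trio_origins(add, geno.samples, ped)
        decided = ~np.isnan(pat)
        assert decided.any()
        np.testing.assert_array_equal(pat[decided], geno.paternal[decided])
        np.testing.assert_array_equal(mat[decided], geno.maternal[decided])
        # ambiguity only where child and both parents are heterozygous
        pos = {s: i for i, s in enumerate(geno.samples)}
        for r in ped.trios().itertuples():
            ci, fi, mi = pos[r.iid], pos[r.father], pos[r.mother]
            amb = np.isnan(pat[ci])
            expected = (add[ci] == 1) & (add[fi] == 1) & (add[mi] == 1)
            np.testing.assert_array_equal(amb, expected)


@pytest.fixture(scope="module")
def paternal_cohort():
    """Pure paternal-imprinting architecture on 3,000 trios."""
    ped = trio_pedigree(3000)
    spec = ArchitectureSpec(
        causal=(CausalVariant("var1", "paternal", a_p=0.4),), background_h2=0.4
    )
    cohort = simulate_cohort(ped, spec, 3, maf_range=(0.2, 0.4), seed=61)
    y = standardize_quiet(cohort.phenotypes["height"])
    return ped, cohort, y


class TestTransmissionTable:
    def test_alleles_reconstruct_parent_genotypes(self, paternal_cohort):
        ped, cohort, _ = paternal_cohort
        tt = transmission_table(cohort.genotypes, ped, "var1")
        pos = {s: i for i, s in enumerate(cohort.genotypes.samples)}
        add = cohort.genotypes.additive()
        fathers = dict(zip(ped.trios()["iid"], ped.trios()["father"]))
        mothers = dict(zip(ped.trios()["iid"], ped.trios()["mother"]))
        j = cohort.genotypes.variant_index("var1")
        for r in tt.itertuples():
            assert r.t_pat + r.nt_pat == add[pos[fathers[r.iid]], j]
            assert r.t_mat + r.nt_mat == add[pos[mothers[r.iid]], j]


class TestNontransmittedTest:
    def test_pure_imprinting_loads_only_on_transmitted_paternal(self, paternal_cohort):
        ped, cohort, y = paternal_cohort
        tt = transmission_table(cohort.genotypes, ped, "var1")
        res = nontransmitted_test(y, tt).set_index("allele")
        t_pat = res.loc["t_pat"]
        assert abs(t_pat["effect"] - 0.4) < 2 * t_pat["se"] + 0.05
        for allele in ("nt_pat", "nt_mat"):
            row = res.loc[allele]
            assert abs(row["effect"]) < 3 * row["se"]

    def test_maternal_genotype_effect_shows_on_nontransmitted_maternal(self):
        ped = trio_pedigree(4000)
        spec = ArchitectureSpec(
            causal=(CausalVariant("var1", "additive", a=0.0, maternal_genotype=0.3),),
            background_h2=0.0,
        )
        cohort = simulate_cohort(ped, spec, 2, maf_range=(0.3, 0.4), seed=71)
        y = standardize_quiet(cohort.phenotypes["height"])
        tt = transmission_table(cohort.genotypes, ped, "var1")
        res = nontransmitted_test(y, tt).set_index("allele")
        # both maternal alleles make up the mother's genotype: each carries
        # the full per-allele effect; paternal columns stay null
        assert abs(res.loc["nt_mat", "effect"] - 0.3) < 2 * res.loc["nt_mat", "se"] + 0.03
        assert abs(res.loc["nt_pat", "effect"]) < 3 * res.loc["nt_pat", "se"]

    def test_null_effects_give_uniform_p(self):
        ped = trio_pedigree(200)
        cohort = simulate_cohort(
            ped, ArchitectureSpec(causal=(), background_h2=0.0), 1,
            maf_range=(0.3, 0.5), seed=81,
        )
        rng = np.random.default_rng(17)
        tt = transmission_table(cohort.genotypes, ped, "var1")
        ps = []
        for rep in range(200):
            y = pd.Series(
                rng.normal(size=cohort.genotypes.n_samples),
                index=cohort.genotypes.samples,
            )
            res = nontransmitted_test(y, tt)
            ps.extend(res["p"].tolist())
        ps = np.array(ps)
        rate = (ps < 0.05).mean()
        assert 0.03 < rate < 0.07

    def test_few_trios_flagged_low_power(self):
        ped = trio_pedigree(10)
        cohort = simulate_cohort(
            ped, ArchitectureSpec(causal=()), 1, maf_range=(0.4, 0.5), seed=91
        )
        y = standardize_quiet(cohort.phenotypes["height"])
        tt = transmission_table(cohort.genotypes, ped, "var1")
        res = nontransmitted_test(y, tt)
        assert res["low_power"].all()


class TestOrderedGenotypeSummary:
    def test_ci_formula_with_correction_factor(self, paternal_cohort):
        _, cohort, y = paternal_cohort
        cf = CorrectionFactor({"additive": 1.48})
        summary = ordered_genotype_summary(y, cohort.genotypes, "var1", cf=cf)
        for r in summary.itertuples():
            if r.n > 1:
                half = 1.96 * r.se * np.sqrt(1.48)
                assert r.ci_low == pytest.approx(r.mean - half)
                assert r.ci_high == pytest.approx(r.mean + half)
        # 1.96 * 0.1 * sqrt(1.48) = 0.2385
        assert 1.96 * 0.1 * np.sqrt(1.48) == pytest.approx(0.2385, abs=5e-4)

    def test_unit_cf_reduces_to_standard_interval(self, paternal_cohort):
        _, cohort, y = paternal_cohort
        s = ordered_genotype_summary(y, cohort.genotypes, "var1", cf=1.0)
        r = s.loc[s["n"] > 1].iloc[0]
        assert r["ci_high"] - r["mean"] == pytest.approx(1.96 * r["se"])

    def test_group_means_conserve_overall_mean(self, paternal_cohort):
        _, cohort, y = paternal_cohort
        s = ordered_genotype_summary(y, cohort.genotypes, "var1")
        total = (s["n"] * s["mean"].fillna(0)).sum() / s["n"].sum()
        yv = y.reindex(cohort.genotypes.samples)
        assert total == pytest.approx(yv.mean(), abs=1e-10)
        assert s["n"].sum() == yv.notna().sum()

    def test_opposing_effects_peak_between_heterozygotes(self):
        ped = trio_pedigree(6000)
        a_p, a_m = -0.5, 0.35
        spec = ArchitectureSpec(
            causal=(CausalVariant("var1", "opposing", a_p=a_p, a_m=a_m),),
            background_h2=0.2,
        )
        cohort = simulate_cohort(ped, spec, 2, maf_range=(0.3, 0.4), seed=95)
        y = standardize_quiet(cohort.phenotypes["height"])
        s = ordered_genotype_summary(y, cohort.genotypes, "var1").set_index("genotype")
        het_gap = abs(s.loc["1|0", "mean"] - s.loc["0|1", "mean"])
        hom_gap = abs(s.loc["1|1", "mean"] - s.loc["0|0", "mean"])
        assert het_gap > hom_gap
        pooled_se = np.sqrt(s.loc["1|0", "se"] ** 2 + s.loc["0|1", "se"] ** 2)
        assert abs(het_gap - (abs(a_p) + abs(a_m))) < 2 * pooled_se + 0.05

    def test_low_info_variant_rejected(self, paternal_cohort):
        _, cohort, y = paternal_cohort
        geno = cohort.genotypes.subset_variants(np.arange(2))
        geno.variants.loc[0, "info"] = 0.5
        with pytest.raises(ValueError, match="info"):
            ordered_genotype_summary(y, geno, "var1")
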