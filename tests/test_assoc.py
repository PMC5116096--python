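"""Association engine: dosage construction, GLS against the
explicit-inverse oracle, the parental contrast, and scan filters."""

import numpy as np
import pandas as pd
import pytest

from poegwas.assoc import (
    AssociationResult,
    ModelDosage,
    Whitener,
    build_dosage,
    genome_scan,
    gls_fit,
)
from poegwas.assoc import test_parent_contrast as parent_contrast
from poegwas.core import OrderedGenotypeMatrix, Pedigree
from poegwas.kinship import partition_clusters, pedigree_kinship
from poegwas.synthetic import (
    ArchitectureSpec,
    CausalVariant,
    founder_pedigree,
    simulate_cohort,
)

from conftest import standardize_quiet


def _matrix(pat, mat, info=None):
    pat = np.asarray(pat, dtype=float)
    n, m = pat.shape
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(m) + 1) * 1000,
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "C",
            "info": 1.0 if info is None else info,
        }
    )
    return OrderedGenotypeMatrix(
        [f"s{i}" for i in range(n)], variants, pat, np.asarray(mat, dtype=float)
    )


class TestBuildDosage:
    def test_ordered_one_zero(self):
        g = _matrix([[1.0]], [[0.0]])
        assert build_dosage(g, "v0", "additive").values[0] == 1.0
        assert build_dosage(g, "v0", "paternal").values[0] == 1.0
        assert build_dosage(g, "v0", "maternal").values[0] == 0.0
        assert build_dosage(g, "v0", "recessive").values[0] == 0.0

    def test_homozygote_is_recessive_one(self):
        g = _matrix([[1.0]], [[1.0]])
        assert build_dosage(g, "v0", "recessive").values[0] == 1.0

    def test_mean_additive_dosage_is_twice_frequency(self, founder_cohort):
        cohort, *_ = founder_cohort
        d = build_dosage(cohort.genotypes, "var3", "additive")
        f = cohort.genotypes.allele_frequency()[2]
        assert np.nanmean(d.values) == pytest.approx(2 * f, abs=1e-12)

    def test_missing_ordered_data_raises(self):
        g = _matrix([[np.nan]], [[np.nan]])
        with pytest.raises(ValueError, match="ordered"):
            build_dosage(g, "v0", "paternal")


def _explicit_gls(y, g, K):
    """Brute-force oracle: (X' K^-1 X)^-1 X' K^-1 y by explicit inversion."""
    Ki = np.linalg.inv(K)
    X = np.column_stack([np.ones_like(g), g])
    beta = np.linalg.solve(X.T @ Ki @ X, X.T @ Ki @ y)
    resid = y - X @ beta
    sigma2 = resid @ Ki @ resid / len(y)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ Ki @ X)[1, 1])
    return beta, sigma2, se


class TestGlsFit:
    def test_identity_kinship_equals_ols(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        d = build_dosage(cohort.genotypes, "var1", "additive")
        res = gls_fit(y, d, kin, part)
        X = np.column_stack([np.ones(len(d.values)), d.values])
        yv = y.reindex(d.samples).to_numpy()
        b, *_ = np.linalg.lstsq(X, yv, rcond=None)
        assert res.beta == pytest.approx(b[1], abs=1e-10)
        assert res.alpha == pytest.approx(b[0], abs=1e-10)

    def test_matches_explicit_inverse_on_sib_pairs(self):
        # two sib pairs, hand-built K
        rows = [
            ("A", "a1", "0", "0", 1), ("A", "a2", "0", "0", 2),
            ("A", "k1", "a1", "a2", 1), ("A", "k2", "a1", "a2", 2),
            ("B", "b1", "0", "0", 1), ("B", "b2", "0", "0", 2),
            ("B", "k3", "b1", "b2", 1), ("B", "k4", "b1", "b2", 2),
        ]
        ped = Pedigree(pd.DataFrame(rows, columns=["fam", "iid", "father", "mother", "sex"]))
        kin = pedigree_kinship(ped)
        part = partition_clusters(ped)
        rng = np.random.default_rng(7)
        g = ModelDosage(
            "additive", "v", rng.integers(0, 3, size=8).astype(float), ped.iids
        )
        y = pd.Series(rng.normal(size=8), index=ped.iids)
        res = gls_fit(y, g, kin, part)
        order = [i for c in part for i in c]
        pos = {s: i for i, s in enumerate(ped.iids)}
        K = kin.submatrix(order)
        beta, sigma2, se = _explicit_gls(
            y.reindex(order).to_numpy(), g.values[[pos[i] for i in order]], K
        )
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.alpha == pytest.approx(beta[0], abs=1e-10)
        assert res.sigma2 == pytest.approx(sigma2, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)

    def test_chi2_identity_and_p_tail(self, trio_cohort):
        cohort, kin, part, y = trio_cohort
        d = build_dosage(cohort.genotypes, "var1", "paternal")
        res = gls_fit(y, d, kin, part)
        assert res.chi2 == pytest.approx((res.beta / res.se) ** 2, abs=1e-8)
        from scipy.stats import chi2 as chi2_dist

        assert res.p == pytest.approx(chi2_dist.sf(res.chi2, 1), abs=1e-12)

    def test_chi2_invariant_to_trait_scale(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        d = build_dosage(cohort.genotypes, "var1", "additive")
        r1 = gls_fit(y, d, kin, part)
        r2 = gls_fit(2.0 * y, d, kin, part)
        assert r2.chi2 == pytest.approx(r1.chi2, rel=1e-10)
        assert r2.beta == pytest.approx(2.0 * r1.beta, rel=1e-10)

    def test_zero_variance_dosage_flagged_untestable(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        d = ModelDosage(
            "additive", "flat", np.zeros(cohort.genotypes.n_samples),
            list(cohort.genotypes.samples),
        )
        res = gls_fit(y, d, kin, part)
        assert res.untestable

    def test_additive_beta_between_parental_betas_noise_free(self):
        # projection property on a noise-free phenotype
        ped = founder_pedigree(4000)
        spec = ArchitectureSpec(
            causal=(CausalVariant("var1", "opposing", a_p=-0.4, a_m=0.1),),
            background_h2=0.0,
        )
        cohort = simulate_cohort(ped, spec, 2, seed=3)
        geno = cohort.genotypes
        yv = -0.4 * geno.paternal[:, 0] + 0.1 * geno.maternal[:, 0]
        y = pd.Series(yv, index=geno.samples)
        kin = pedigree_kinship(ped)
        part = partition_clusters(ped)
        b = {
            m: gls_fit(y, build_dosage(geno, "var1", m), kin, part).beta
            for m in ("additive", "paternal", "maternal")
        }
        lo, hi = sorted([b["paternal"], b["maternal"]])
        assert lo - 1e-6 <= b["additive"] <= hi + 1e-6


class TestParentContrast:
    def test_null_when_parental_effects_equal(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        dp = build_dosage(cohort.genotypes, "var2", "paternal")
        dm = build_dosage(cohort.genotypes, "var2", "maternal")
        res = parent_contrast(y, dp, dm, kin, part)
        assert not res.untestable
        assert res.p > 1e-4  # var2 is a null variant

    def test_degenerate_maternal_dosage_flagged(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        dp = build_dosage(cohort.genotypes, "var2", "paternal")
        dm = ModelDosage(
            "maternal", "var2", np.zeros_like(dp.values), dp.samples
        )
        res = parent_contrast(y, dp, dm, kin, part)
        assert res.untestable

    def test_collinear_parental_dosages_flagged(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        dp = build_dosage(cohort.genotypes, "var2", "paternal")
        dm = ModelDosage("maternal", "var2", dp.values.copy(), dp.samples)
        res = parent_contrast(y, dp, dm, kin, part)
        assert res.untestable
        assert "collinear" in res.note


class TestGenomeScan:
    def test_low_info_variant_excluded_everywhere(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        geno = cohort.genotypes.subset_variants(np.arange(3))
        geno.variants.loc[1, "info"] = 0.5
        frame = genome_scan(geno, y, kin, part)
        rows = frame.loc[frame["variant"] == "var2"]
        assert rows["untestable"].all()
        assert rows["note"].str.contains("info").all()

    def test_recessive_needs_minor_homozygote(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        geno = cohort.genotypes.subset_variants(np.arange(2))
        # remove all minor-allele homozygotes at var2
        hom = (geno.paternal[:, 1] >= 1) & (geno.maternal[:, 1] >= 1)
        geno.maternal[hom, 1] = 0.0
        frame = genome_scan(geno, y, kin, part)
        row = frame.loc[(frame["variant"] == "var2") & (frame["model"] == "recessive")]
        assert row["untestable"].all()
        assert row["note"].str.contains("homozygote").all()

    def test_monomorphic_variant_untestable_under_all_models(self, founder_cohort):
        cohort, kin, part, y = founder_cohort
        geno = cohort.genotypes.subset_variants(np.arange(2))
        geno.paternal[:, 1] = 0.0
        geno.maternal[:, 1] = 0.0
        frame = genome_scan(geno, y, kin, part)
        assert frame.loc[frame["variant"] == "var2", "untestable"].all()

    def test_best_model_has_lowest_p(self, trio_cohort):
        cohort, kin, part, y = trio_cohort
        geno = cohort.genotypes.subset_variants(np.arange(3))
        frame = genome_scan(geno, y, kin, part)
        for vid, grp in frame.loc[~frame["untestable"]].groupby("variant"):
            best = grp.loc[grp["best"]]
            assert len(best) == 1
            assert best["p"].iloc[0] == grp["p"].min()
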