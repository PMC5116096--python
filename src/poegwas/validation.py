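"""End-to-end validation studies on synthetic cohorts.

The cohort behind the published parent-of-origin height scan is not
public, so the pipeline is validated by property: each function here sets
up a synthetic study with known truth, runs the relevant part of the
pipeline, and returns the measured quantities (type-I error, recovered
effects, intercepts, signal counts, oracle deviations).  The same
functions back both the acceptance test suite and the reporting script.

Problem sizes default to the smallest cohorts at which the checked
properties are statistically sharp; each function takes a seed and is
fully deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .assoc import Whitener, build_dosage, genome_scan, gls_fit, test_parent_contrast
from .calibration import ldsc_intercept
from .imprinting import nontransmitted_test, transmission_table
from .kinship import partition_clusters, pedigree_kinship
from .multiplicity import class_thresholds, opposite_parent_threshold
from .phenotype import adjust_and_standardize, sd_to_units
from .signals import conditional_scan
from .synthetic import (
    ArchitectureSpec,
    CausalVariant,
    SimulatedCohort,
    founder_pedigree,
    simulate_cohort,
    simulate_haplotypes,
    simulate_phenotypes,
    simulate_pedigree,
    trio_pedigree,
)

#: genome-wide variant counts per functional impact class
GENOME_CLASS_COUNTS = {"high": 9_989, "moderate": 170_692, "low": 31_421_778}

#: printed effect conversions: (effect s.d., trait s.d. cm)
UNIT_CONVERSION_CASES = {
    "effect_cm_igf2_h19_a_paternal": (-0.12, 6.6),
    "effect_cm_igf2_h19_b_paternal": (-0.065, 6.6),
    "effect_cm_kcnq1_maternal": (-0.26, 6.6),
    "effect_cm_tet1_adult": (0.48, 6.6),
    "effect_cm_tet1_birth": (0.86, 2.5),
}

GW_LOW_IMPACT = 5.3e-10


def _standardize(phen: pd.DataFrame) -> pd.Series:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = adjust_and_standardize(phen)
    return std.set_index("iid")["y"]


def genome_wide_thresholds() -> dict[str, float]:
    """The three class-specific Bonferroni thresholds at alpha = 0.05 for
    the genome-wide impact-class counts."""
    scheme = class_thresholds(0.05, GENOME_CLASS_COUNTS)
    return {f"threshold_{c}_impact": scheme[c] for c in GENOME_CLASS_COUNTS}


def unit_conversions() -> dict[str, float]:
    """Standardized effects of the lead variants converted to cm."""
    return {
        name: sd_to_units(sd, trait_sd)
        for name, (sd, trait_sd) in UNIT_CONVERSION_CASES.items()
    }


def gls_oracle_max_error(seed: int) -> float:
    """Largest |difference| between the block GLS and the explicit-inverse
    formula (X' K^-1 X)^-1 X' K^-1 y over a batch of <=50-sample pedigree
    fixtures (estimates, intercept, sigma^2 and se compared)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k, ped in enumerate(
        [
            founder_pedigree(20),
            trio_pedigree(8),
            simulate_pedigree(10, 3, mating_rate=1.0, seed=seed + 1),
        ]
    ):
        kin = pedigree_kinship(ped)
        part = partition_clusters(ped)
        n = len(ped)
        geno = simulate_haplotypes(ped, 3, seed=seed + 2 + k, maf_range=(0.2, 0.5))
        y = pd.Series(rng.normal(size=n), index=geno.samples)
        for vid in geno.variants["id"]:
            dose = build_dosage(geno, vid, "additive")
            res = gls_fit(y, dose, kin, part)
            if res.untestable:
                continue
            order = [i for c in part for i in c]
            pos = {s: i for i, s in enumerate(geno.samples)}
            K = kin.submatrix(order)
            Ki = np.linalg.inv(K)
            X = np.column_stack([np.ones(n), dose.values[[pos[i] for i in order]]])
            yv = y.reindex(order).to_numpy()
            beta = np.linalg.solve(X.T @ Ki @ X, X.T @ Ki @ yv)
            resid = yv - X @ beta
            sigma2 = resid @ Ki @ resid / n
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ Ki @ X)[1, 1])
            worst = max(
                worst,
                abs(res.beta - beta[1]),
                abs(res.alpha - beta[0]),
                abs(res.sigma2 - sigma2),
                abs(res.se - se),
            )
    return worst


def null_type1_error(
    seed: int, n_reps: int = 2000, n_trios: int = 400, alpha: float = 0.05
) -> dict[str, float]:
    """Empirical type-I error of the additive, paternal and parental-
    contrast tests on a related null cohort (trio families, polygenic
    background on, no causal variant), with the kinship variance share
    estimated per replicate."""
    ped = trio_pedigree(n_trios)
    kin = pedigree_kinship(ped)
    part = partition_clusters(ped)
    geno = simulate_haplotypes(ped, 10, seed=seed, maf_range=(0.1, 0.5))
    cohort = SimulatedCohort(ped, geno)
    spec = ArchitectureSpec(causal=())
    wh = Whitener(kin, part)
    hits = {"additive": 0, "paternal": 0, "contrast": 0}
    for rep in range(n_reps):
        phen = simulate_phenotypes(cohort, spec, seed=seed + 1 + rep)
        y = _standardize(phen)
        wh.theta = wh.estimate_theta(y.reindex(wh.samples).to_numpy())
        vid = geno.variants["id"][rep % geno.n_variants]
        dp = build_dosage(geno, vid, "paternal")
        dm = build_dosage(geno, vid, "maternal")
        da = build_dosage(geno, vid, "additive")
        if gls_fit(y, da, kin, part, whitener=wh).p < alpha:
            hits["additive"] += 1
        if gls_fit(y, dp, kin, part, whitener=wh).p < alpha:
            hits["paternal"] += 1
        if test_parent_contrast(y, dp, dm, kin, part, whitener=wh).p < alpha:
            hits["contrast"] += 1
    return {f"type1_{k}": v / n_reps for k, v in hits.items()}


def imprinting_recovery(
    seed: int, n_trios: int = 10_000, a_p: float = 0.4
) -> dict[str, float]:
    """Pure paternal-imprinting simulation: the transmitted paternal
    allele should recover a_p and the non-transmitted alleles should be
    null.  Returns effects, standard errors and |z| of the null columns."""
    ped = trio_pedigree(n_trios)
    spec = ArchitectureSpec(
        causal=(CausalVariant("var1", "paternal", a_p=a_p),), background_h2=0.4
    )
    cohort = simulate_cohort(ped, spec, 2, maf_range=(0.2, 0.4), seed=seed)
    y = _standardize(cohort.phenotypes["height"])
    tt = transmission_table(cohort.genotypes, ped, "var1")
    res = nontransmitted_test(y, tt).set_index("allele")
    return {
        "transmitted_paternal_effect": float(res.loc["t_pat", "effect"]),
        "transmitted_paternal_se": float(res.loc["t_pat", "se"]),
        "transmitted_paternal_true": a_p,
        "nontransmitted_paternal_abs_z": float(
            abs(res.loc["nt_pat", "effect"] / res.loc["nt_pat", "se"])
        ),
        "nontransmitted_maternal_abs_z": float(
            abs(res.loc["nt_mat", "effect"] / res.loc["nt_mat", "se"])
        ),
    }


def opposing_effect_study(
    seed: int,
    n: int = 90_000,
    a_p: float = -0.12,
    a_m: float = 0.056,
    f: float = 0.05,
) -> dict[str, float]:
    """The opposing parental effect study condition: a variant whose minor
    allele lowers the trait paternally but raises it maternally.  The
    paternal test should reach genome-wide-scale significance while the
    additive test (which sees only the average (a_p + a_m)/2) should not."""
    ped = founder_pedigree(n)
    kin = pedigree_kinship(ped)
    part = partition_clusters(ped)
    spec = ArchitectureSpec(
        causal=(CausalVariant("var1", "opposing", a_p=a_p, a_m=a_m),)
    )
    cohort = simulate_cohort(
        ped, spec, 3, seed=seed, frequencies=np.full(3, f)
    )
    y = _standardize(cohort.phenotypes["height"])
    wh = Whitener(kin, part)
    geno = cohort.genotypes
    da = build_dosage(geno, "var1", "additive")
    dp = build_dosage(geno, "var1", "paternal")
    dm = build_dosage(geno, "var1", "maternal")
    ra = gls_fit(y, da, kin, part, whitener=wh)
    rp = gls_fit(y, dp, kin, part, whitener=wh)
    rm = gls_fit(y, dm, kin, part, whitener=wh)
    rc = test_parent_contrast(y, dp, dm, kin, part, whitener=wh)
    return {
        "p_paternal": rp.p,
        "p_maternal": rm.p,
        "p_additive": ra.p,
        "p_contrast": rc.p,
        "beta_paternal": rp.beta,
        "beta_maternal": rm.beta,
        "log10_p_paternal": float(np.log10(rp.p)) if rp.p > 0 else -np.inf,
    }


def ldsc_intercept_recovery(
    seed: int, n_variants: int = 10_000, inflation: float = 1.5
) -> dict[str, float]:
    """Intercept of the LD score regression on (a) i.i.d. chi-squared(1)
    statistics (expected 1) and (b) the same statistics multiplied by a
    constant inflation factor (expected the factor)."""
    rng = np.random.default_rng(seed)
    stats = chi2_dist.rvs(1, size=n_variants, random_state=rng)
    ell = rng.uniform(1, 10, size=n_variants)
    frame = pd.DataFrame(
        {
            "variant": [f"v{i}" for i in range(n_variants)],
            "model": "additive",
            "chi2": stats,
            "untestable": False,
        }
    )
    scores = pd.DataFrame({"id": frame["variant"], "ldscore": ell})
    null_icpt = ldsc_intercept(frame, scores)["additive"]
    inflated = frame.assign(chi2=inflation * stats)
    infl_icpt = ldsc_intercept(inflated, scores)["additive"]
    # standard error of the intercept under the null fit
    x = np.column_stack([np.ones(n_variants), ell])
    resid = stats - x @ np.linalg.lstsq(x, stats, rcond=None)[0]
    cov = np.linalg.inv(x.T @ x) * (resid @ resid) / (n_variants - 2)
    return {
        "ldsc_intercept_null": float(null_icpt),
        "ldsc_intercept_inflated": float(infl_icpt),
        "ldsc_inflation_applied": inflation,
        "ldsc_intercept_se": float(np.sqrt(cov[0, 0])),
    }


def conditional_scan_recovery(
    seed: int,
    n_reps: int = 200,
    n: int = 10_000,
    effect: float = 0.5,
    reps_per_genotype_draw: int = 10,
) -> dict[str, float]:
    """Truth recovery of the iterative conditional analysis over replicated
    simulations.

    Scenario A: two causal variants in uncorrelated LD blocks of one
    region - the scan should report exactly two independent signals.
    Scenario B: one causal variant plus a strong proxy (target r^2 = 0.9)
    - the scan should collapse them to one signal.  Returns the fraction
    of replicates with the correct signal count.
    """
    ped = founder_pedigree(n)
    kin = pedigree_kinship(ped)
    part = partition_clusters(ped)
    counts = {"two_causals": [], "causal_plus_proxy": []}
    specs = {
        "two_causals": (
            ArchitectureSpec(
                causal=(
                    CausalVariant("var1", "additive", a=effect),
                    CausalVariant("var6", "additive", a=effect),
                ),
                background_h2=0.0,
            ),
            dict(ld_block_size=5, target_r2=0.5),
            2,
        ),
        "causal_plus_proxy": (
            ArchitectureSpec(
                causal=(CausalVariant("var1", "additive", a=effect),),
                background_h2=0.0,
            ),
            dict(ld_block_size=2, target_r2=0.9),
            1,
        ),
    }
    for name, (spec, ld_kw, expected) in specs.items():
        rep = 0
        draw = 0
        while rep < n_reps:
            geno = simulate_haplotypes(
                ped, 10, maf_range=(0.2, 0.4), seed=seed + 1000 * draw, **ld_kw
            )
            cohort = SimulatedCohort(ped, geno)
            wh = Whitener(kin, part)
            for _ in range(reps_per_genotype_draw):
                if rep >= n_reps:
                    break
                phen = simulate_phenotypes(cohort, spec, seed=seed + 7919 * rep + 1)
                y = _standardize(phen)
                results = genome_scan(
                    geno, y, kin, part, models=("additive",), whitener=wh
                )
                sigs = conditional_scan(
                    results, geno, y, kin, part, GW_LOW_IMPACT, whitener=wh
                )
                counts[name].append(len(sigs) == expected)
                rep += 1
            draw += 1
    return {
        "conditional_two_causals_correct": float(np.mean(counts["two_causals"])),
        "conditional_proxy_collapsed": float(np.mean(counts["causal_plus_proxy"])),
    }


def kinship_gene_dropping_check(
    seed: int, n_drops: int = 100_000
) -> dict[str, float]:
    """Recursive kinship against a gene-dropping Monte-Carlo oracle on a
    three-generation pedigree; returns the worst absolute deviation and
    the worst deviation in Monte-Carlo standard-error units."""
    ped = simulate_pedigree(8, 3, mating_rate=1.0, seed=seed)
    kin = pedigree_kinship(ped)
    rng = np.random.default_rng(seed + 1)
    order = ped.topological_order()
    founders = set(ped.founders())
    parent_of = {r.iid: (r.father, r.mother) for r in ped.table.itertuples()}
    alleles: dict[str, np.ndarray] = {}
    label = 0
    for iid in order:
        if iid in founders:
            alleles[iid] = np.tile([label, label + 1], (n_drops, 1))
            label += 2
        else:
            f, m = parent_of[iid]
            pa = alleles[f][np.arange(n_drops), rng.integers(2, size=n_drops)]
            ma = alleles[m][np.arange(n_drops), rng.integers(2, size=n_drops)]
            alleles[iid] = np.column_stack([pa, ma])
    worst_abs = worst_z = 0.0
    grandchildren = [i for i in order if parent_of[i][0] not in founders | {"0"}][:6]
    others = order[:4] + grandchildren
    pairs = [(a, b) for i, a in enumerate(others) for b in others[i + 1 :]]
    for a, b in pairs:
        pick_a = alleles[a][np.arange(n_drops), rng.integers(2, size=n_drops)]
        pick_b = alleles[b][np.arange(n_drops), rng.integers(2, size=n_drops)]
        est = (pick_a == pick_b).mean()
        se = max(np.sqrt(est * (1 - est) / n_drops), 1e-4)
        dev = abs(est - kin.phi_pair(a, b))
        worst_abs = max(worst_abs, dev)
        worst_z = max(worst_z, dev / se)
    return {
        "kinship_worst_abs_deviation": worst_abs,
        "kinship_worst_z": worst_z,
    }
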