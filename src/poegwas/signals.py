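"""Independent signals: conditional analysis, classification, variance explained.

A genome-wide significant region (lead variant +/- 2 Mb) may harbour one or
several statistically independent associations.  The lead variant (lowest
P) is added as a covariate to the kinship GLS and every well-imputed
variant (info > 0.9) in the region is retested; any variant whose adjusted
P remains genome-wide significant marks a further independent signal, and
the procedure repeats until none remains.  Each signal is then classified
against a catalogue of previously reported variants (reported / refinement
/ novel, based on LD and conditional fits) and its fraction of phenotypic
variance is computed from the allele frequency and the standardized effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import AssociationResult, Whitener, build_dosage, gls_fit
from .core import OrderedGenotypeMatrix
from .kinship import ClusterPartition, KinshipMatrix

CONDITIONAL_WINDOW = 2_000_000  # +/- 2 Mb
CATALOGUE_WINDOW = 500_000  # +/- 500 kb
CONDITIONAL_INFO_MIN = 0.9
REFINEMENT_RESIDUAL_P = 1.0e-3
LD_NOVEL = 0.10
LD_REFINEMENT = 0.80
POE_INCLUSION_P = 1.0e-2

PARENTAL_MODELS = ("paternal", "maternal")


def _threshold_of(threshold, variant: str) -> float:
    if callable(threshold):
        return float(threshold(variant))
    if isinstance(threshold, dict):
        return float(threshold[variant])
    return float(threshold)


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3 or np.var(a[ok]) == 0 or np.var(b[ok]) == 0:
        return np.nan
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(r * r)


def _conditional_fit(
    genotypes: OrderedGenotypeMatrix,
    y: pd.Series,
    kin: KinshipMatrix,
    partition: ClusterPartition,
    variant: str,
    model: str,
    conditioning: list[str],
    whitener: Whitener | None = None,
) -> AssociationResult:
    """GLS fit of one variant with the conditioning set as covariates.

    For the parental models each conditioning variant contributes both of
    its haplotype dosages as covariates, so that the lead absorbs its
    signal whether it is additive or parent-of-origin specific (an
    additive covariate alone averages the haplotypes and leaves a
    parental residue, while one haplotype alone leaves the other's).
    For the additive and recessive models the additive dosage is used
    (it captures LD better than a homozygote indicator)."""
    dose = build_dosage(genotypes, variant, model)
    cov = None
    if conditioning:
        cols: dict[str, np.ndarray] = {}
        for c in conditioning:
            if model in PARENTAL_MODELS:
                cols[f"{c}:pat"] = build_dosage(genotypes, c, "paternal").values
                cols[f"{c}:mat"] = build_dosage(genotypes, c, "maternal").values
            else:
                cols[c] = build_dosage(genotypes, c, "additive").values
        cov = pd.DataFrame(cols, index=genotypes.samples)
        for c, col in cols.items():
            r2 = _r2(dose.values, col)
            if np.isnan(r2) or r2 > 0.999:
                return AssociationResult(
                    variant=variant, model=model, untestable=True,
                    note=f"collinear with conditioning variant {c}",
                )
    return gls_fit(y, dose, kin, partition, whitener=whitener, covariates=cov)


def conditional_scan(
    results: pd.DataFrame,
    genotypes: OrderedGenotypeMatrix,
    y: pd.Series,
    kin: KinshipMatrix,
    partition: ClusterPartition,
    threshold,
    window: int = CONDITIONAL_WINDOW,
    info_min: float = CONDITIONAL_INFO_MIN,
    p_column: str = "p",
    whitener: Whitener | None = None,
    theta: float = 1.0,
) -> pd.DataFrame:
    """Iterative conditional analysis of every significant region.

    ``results`` is an association frame for a single model; ``threshold``
    is a scalar, per-variant dict, or callable giving the genome-wide
    significance threshold of each variant.  Ties on P break towards the
    smaller genomic position.  Returns one row per independent signal
    (columns ``variant, model, chrom, pos, p, p_adjusted, rank, region_start,
    region_end``); empty frame if nothing is significant.
    """
    res = results.loc[~results.get("untestable", False)].copy()
    if res.empty:
        return _empty_signals()
    if whitener is None:
        have_y = set(y.dropna().index) & set(genotypes.samples)
        whitener = Whitener(kin, partition, include=have_y, theta=theta)
    models = res["model"].unique()
    if len(models) != 1:
        raise ValueError("conditional_scan expects results for a single model")
    model = models[0]
    meta = genotypes.variants.set_index("id")
    res = res.join(meta[["chrom", "pos", "info"]], on="variant")
    res = res.dropna(subset=[p_column])

    sig = res.loc[
        [p < _threshold_of(threshold, v) for v, p in zip(res["variant"], res[p_column])]
    ].copy()
    rows: list[dict] = []
    remaining = sig.sort_values([p_column, "pos"], kind="mergesort")
    while not remaining.empty:
        lead = remaining.iloc[0]
        chrom, centre = lead["chrom"], lead["pos"]
        lo, hi = centre - window, centre + window
        in_region = (
            (res["chrom"] == chrom) & (res["pos"] >= lo) & (res["pos"] <= hi)
        )
        region = res.loc[in_region & (res["info"] > info_min)]
        conditioning = [lead["variant"]]
        rows.append(
            {
                "variant": lead["variant"], "model": model,
                "chrom": chrom, "pos": centre,
                "p": lead[p_column], "p_adjusted": lead[p_column],
                "rank": 1, "region_start": lo, "region_end": hi,
            }
        )
        # iterate: retest the region conditional on the signals found so far
        while True:
            best = None
            for r in region.itertuples():
                if r.variant in conditioning:
                    continue
                fit = _conditional_fit(
                    genotypes, y, kin, partition, r.variant, model,
                    conditioning, whitener=whitener,
                )
                if fit.untestable or not np.isfinite(fit.p):
                    continue
                key = (fit.p, r.pos)
                if best is None or key < best[0]:
                    best = (key, r.variant, fit.p, r.chrom, r.pos)
            if best is None:
                break
            _, vid, p_adj, vchrom, vpos = best
            if p_adj >= _threshold_of(threshold, vid):
                break
            conditioning.append(vid)
            rows.append(
                {
                    "variant": vid, "model": model, "chrom": vchrom, "pos": vpos,
                    "p": float(res.loc[res["variant"] == vid, p_column].iloc[0]),
                    "p_adjusted": p_adj, "rank": len(conditioning),
                    "region_start": lo, "region_end": hi,
                }
            )
        remaining = remaining.loc[
            ~(
                (remaining["chrom"] == chrom)
                & (remaining["pos"] >= lo)
                & (remaining["pos"] <= hi)
            )
        ]
    return pd.DataFrame(rows, columns=_empty_signals().columns)


def _empty_signals() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "variant", "model", "chrom", "pos", "p", "p_adjusted",
            "rank", "region_start", "region_end",
        ]
    )


def classify_signal(
    signal: pd.Series,
    catalogue: pd.DataFrame,
    genotypes: OrderedGenotypeMatrix,
    y: pd.Series,
    kin: KinshipMatrix,
    partition: ClusterPartition,
    threshold,
    window: int = CATALOGUE_WINDOW,
    whitener: Whitener | None = None,
) -> tuple[str, str]:
    """Three-way classification of a signal against reported variants.

    Only catalogue entries under the same model and within +/- ``window``
    of the signal are considered.  The rules, applied with LD (r^2 between
    additive dosages) and conditional GLS fits:

    * novel - no reported correlate with r^2 >= 0.10, and conditioning on
      all nearby reported variants leaves the signal genome-wide
      significant (reported variants cannot account for its effect);
    * refinement - a reported correlate exists at 0.10 < r^2 < 0.80, the
      signal associates more strongly than every reported correlate and
      accounts for their effects (their P adjusted for the signal rises
      above 1e-3), while they cannot fully account for the signal
      (its adjusted P < 1e-3);
    * reported - otherwise (e.g. r^2 >= 0.80, or the reported set absorbs
      the signal).

    Returns ``(classification, note)``; a catalogue variant absent from
    the genotype matrix makes LD unknown and forces a conservative
    ``reported`` call with a review note.
    """
    if whitener is None:
        have_y = set(y.dropna().index) & set(genotypes.samples)
        whitener = Whitener(kin, partition, include=have_y)
    model = signal["model"]
    chrom, pos = signal["chrom"], signal["pos"]
    nearby = catalogue.loc[
        (catalogue["model"] == model)
        & (catalogue["chrom"].astype(str) == str(chrom))
        & ((catalogue["pos"] - pos).abs() <= window)
    ]
    if nearby.empty:
        return "novel", "no reported variant under this model within window"

    known_ids = set(genotypes.variants["id"])
    missing = [v for v in nearby["id"] if v not in known_ids]
    if missing:
        return "reported", f"catalogue variant(s) {missing} not in genotypes; LD unknown"

    add = genotypes.additive()
    sig_dose = add[:, genotypes.variant_index(signal["variant"])]
    r2 = {
        v: _r2(sig_dose, add[:, genotypes.variant_index(v)]) for v in nearby["id"]
    }
    max_r2 = max(r2.values())
    gw = _threshold_of(threshold, signal["variant"])

    if max_r2 < LD_NOVEL:
        fit = _conditional_fit(
            genotypes, y, kin, partition, signal["variant"], model,
            list(nearby["id"]), whitener=whitener,
        )
        if not fit.untestable and np.isfinite(fit.p) and fit.p < gw:
            return "novel", f"max r2 {max_r2:.3f} < {LD_NOVEL}; adjusted P {fit.p:.3g}"
        return "reported", "reported variants account for the effect"

    moderate = [v for v, q in r2.items() if LD_NOVEL < q < LD_REFINEMENT]
    strong = [v for v, q in r2.items() if q >= LD_REFINEMENT]
    if moderate and not strong:
        # signal conditioned on all reported correlates: residual effect?
        fit_sig = _conditional_fit(
            genotypes, y, kin, partition, signal["variant"], model,
            moderate, whitener=whitener,
        )
        residual = (
            not fit_sig.untestable
            and np.isfinite(fit_sig.p)
            and fit_sig.p < REFINEMENT_RESIDUAL_P
        )
        stronger = True
        absorbs = True
        for v in moderate:
            marg = gls_fit(
                y, build_dosage(genotypes, v, model), kin, partition,
                whitener=whitener,
            )
            if not (np.isfinite(marg.p) and signal["p"] < marg.p):
                stronger = False
            cond = _conditional_fit(
                genotypes, y, kin, partition, v, model, [signal["variant"]],
                whitener=whitener,
            )
            if not cond.untestable and np.isfinite(cond.p) and cond.p < REFINEMENT_RESIDUAL_P:
                absorbs = False
        if residual and stronger and absorbs:
            return "refinement", f"moderate correlates {moderate}"
    return "reported", f"max r2 {max_r2:.3f} with reported variants"


def variance_explained(
    model: str,
    f: float | None = None,
    a: float | None = None,
    f_h: float | None = None,
    a_r: float | None = None,
    a_p: float | None = None,
    a_m: float | None = None,
    p_p: float | None = None,
    p_m: float | None = None,
    inclusion_p: float = POE_INCLUSION_P,
) -> float:
    """Fraction of phenotypic variance explained by one signal.

    With effects in s.d. units of the standardized trait:

    * additive: 2 f (1-f) a^2  (f = minor allele frequency);
    * recessive: f_h (1-f_h) a_r^2  (f_h = homozygote frequency);
    * paternal / maternal / opposing: f (1-f) (a_p^2 + a_m^2), where a
      parental effect enters only if that model's P < ``inclusion_p``
      (1e-2); the other term is zeroed.

    These are the variances of the corresponding regressors: 2f(1-f) for
    an additive count, f_h(1-f_h) for a homozygote indicator, and f(1-f)
    for each of two independent Bernoulli(f) parental alleles.
    """
    if model == "additive":
        _check_fraction("f", f)
        return 2.0 * f * (1.0 - f) * a**2
    if model == "recessive":
        _check_fraction("f_h", f_h)
        return f_h * (1.0 - f_h) * a_r**2
    if model in PARENTAL_MODELS or model == "opposing":
        _check_fraction("f", f)
        ap = a_p if (a_p is not None and p_p is not None and p_p < inclusion_p) else 0.0
        am = a_m if (a_m is not None and p_m is not None and p_m < inclusion_p) else 0.0
        return f * (1.0 - f) * (ap**2 + am**2)
    raise ValueError(f"unknown model {model!r}")


def _check_fraction(name: str, value: float | None) -> None:
    if value is None or not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie in (0, 1), got {value}")


def total_variance_explained(per_signal: list[float]) -> float:
    """Total over independent signals, one representative variant each."""
    return float(np.sum(per_signal))
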