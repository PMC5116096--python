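"""LD score regression calibration of the association scan.

Residual inflation of the chi-squared statistics from cryptic relatedness
or stratification is estimated by regressing per-variant chi-squared on LD
score (the sum of squared correlations of a variant with its neighbours,
itself included).  Confounding inflates the intercept while true polygenic
signal inflates the slope; the intercept is therefore used as a
genomic-control-style correction factor, dividing every chi-squared before
P-values are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import OrderedGenotypeMatrix

DEFAULT_WINDOW = 1_000_000  # 1 Mb


@dataclass
class CorrectionFactor:
    """Per-model multiplicative inflation estimates (LDSC intercepts)."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        bad = {m: v for m, v in self.factors.items() if not v > 0}
        if bad:
            raise ValueError(f"correction factors must be positive: {bad}")

    def __getitem__(self, model: str) -> float:
        return self.factors[model]


def compute_ld_scores(
    genotypes: OrderedGenotypeMatrix, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """LD score per variant: ell_j = sum of r^2 with every variant within
    ``window`` bp on the same chromosome, including itself (so ell >= 1).

    r^2 is computed between unordered additive dosages.  Zero-variance
    variants are excluded entirely (no score, and they contribute to no
    other variant's score).  Returns a frame with columns ``id, ldscore``.
    """
    add = genotypes.additive()
    var = np.nanvar(add, axis=0)
    keep = var > 0
    ids = genotypes.variants["id"].to_numpy()[keep]
    chroms = genotypes.variants["chrom"].to_numpy()[keep]
    pos = genotypes.variants["pos"].to_numpy()[keep]
    add = add[:, keep]

    centred = add - np.nanmean(add, axis=0)
    centred = np.where(np.isnan(centred), 0.0, centred)
    norms = np.sqrt((centred**2).sum(axis=0))
    scores = np.zeros(len(ids))
    for c in np.unique(chroms):
        m = chroms == c
        idx = np.flatnonzero(m)
        p = pos[m]
        x = centred[:, m] / norms[m]
        corr = x.T @ x
        in_window = np.abs(p[:, None] - p[None, :]) <= window
        scores[idx] = np.where(in_window, corr**2, 0.0).sum(axis=1)
    return pd.DataFrame({"id": ids, "ldscore": scores})


def ldsc_intercept(
    results: pd.DataFrame,
    scores: pd.DataFrame,
    min_variants: int = 100,
    max_chi2: float | None = None,
) -> CorrectionFactor:
    """Per-model intercept of the unweighted regression chi2 ~ 1 + ldscore.

    ``results`` is an association frame (columns ``variant, model, chi2``);
    variants without an LD score are dropped.  ``max_chi2`` optionally
    excludes large-effect outliers from the regression (the usual
    practice when the variant panel is small enough for single loci to
    dominate the fit).  At least ``min_variants`` variants per model are
    required, and a constant LD score is rejected (no regression slope is
    identifiable — enlarge the window).
    """
    merged = results.loc[~results.get("untestable", False)].merge(
        scores, left_on="variant", right_on="id", how="inner"
    )
    factors: dict[str, float] = {}
    for model, grp in merged.groupby("model"):
        grp = grp.dropna(subset=["chi2", "ldscore"])
        if max_chi2 is not None:
            grp = grp.loc[grp["chi2"] <= max_chi2]
        if len(grp) < min_variants:
            raise ValueError(
                f"model {model!r}: {len(grp)} variants with chi2 and LD score, "
                f"need >= {min_variants}"
            )
        ell = grp["ldscore"].to_numpy()
        if np.ptp(ell) == 0:
            raise ValueError(
                f"model {model!r}: LD scores are constant; enlarge the window"
            )
        x = np.column_stack([np.ones(len(ell)), ell])
        coef, *_ = np.linalg.lstsq(x, grp["chi2"].to_numpy(), rcond=None)
        factors[model] = float(coef[0])
    return CorrectionFactor(factors=factors)


def apply_correction(
    results: pd.DataFrame, cf: CorrectionFactor, allow_deflation: bool = False
) -> pd.DataFrame:
    """Divide chi-squared by the model's correction factor and recompute P.

    Intercepts below 1 indicate no inflation; by default they are clamped
    to 1 (no adjustment) unless ``allow_deflation`` is set.  Adds columns
    ``chi2_corrected`` and ``p_corrected``; the map is monotone, so variant
    ranking within a model is unchanged.
    """
    out = results.copy()
    out["chi2_corrected"] = np.nan
    out["p_corrected"] = np.nan
    for model, factor in cf.factors.items():
        eff = factor if (allow_deflation or factor >= 1.0) else 1.0
        m = (out["model"] == model) & out["chi2"].notna()
        corrected = out.loc[m, "chi2"] / eff
        out.loc[m, "chi2_corrected"] = corrected
        out.loc[m, "p_corrected"] = chi2.sf(corrected, df=1)
    return out
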