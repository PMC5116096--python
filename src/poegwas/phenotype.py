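"""Phenotype adjustment and standardization.

All association effects are reported on the standardized (s.d.) scale.
Raw measurements are residualized on year of birth and rank-inverse-normal
transformed within each stratum (trait x sex x measurement source), so that
each stratum follows a standard normal distribution; conversion back to
physical units multiplies by the trait s.d. (6.6 cm for adult height,
2.5 cm for birth length).
"""

from __future__ import annotations

import decimal
import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: default trait standard deviations in cm
TRAIT_SD = {"height": 6.6, "birth_length": 2.5}

#: Blom offset for the rank-based inverse normal transform
BLOM_OFFSET = 3.0 / 8.0

MIN_STRATUM = 10

STRATA_COLUMNS = ["trait", "sex", "source"]


def inverse_normal(values: np.ndarray, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset by default.

    Maps values to Phi^-1((rank - offset) / (n + 1 - 2*offset)); ties are
    assigned their average rank.  Monotone: rank order is preserved.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    ranks = stats.rankdata(values)
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def _residualize_on_year(values: np.ndarray, year: np.ndarray) -> np.ndarray:
    """Least-squares residual of values on year of birth (with intercept).
    A constant year column degenerates to mean-centering."""
    year = np.asarray(year, dtype=float)
    x = np.column_stack([np.ones_like(year), year - year.mean()])
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def adjust_and_standardize(
    raw: pd.DataFrame,
    strata: list[str] | None = None,
    offset: float = BLOM_OFFSET,
    min_stratum: int = MIN_STRATUM,
) -> pd.DataFrame:
    """Year-of-birth correction and per-stratum inverse-normal transform.

    ``raw`` needs columns ``iid, trait, value, sex, year_of_birth, source``.
    Within each stratum (default trait x sex x source) the values are
    residualized on year of birth by least squares and then rank
    inverse-normal transformed.  Strata below ``min_stratum`` samples are
    dropped with a warning.  Returns the input rows (possibly fewer) with a
    standardized column ``y`` appended; each retained stratum of ``y`` has
    mean ~0 and follows standard normal quantiles.
    """
    strata = STRATA_COLUMNS if strata is None else strata
    required = {"iid", "value", "year_of_birth"} | set(strata)
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")

    out = []
    for key, grp in raw.groupby(strata, sort=False, dropna=False):
        if len(grp) < min_stratum:
            warnings.warn(
                f"stratum {key} has {len(grp)} < {min_stratum} samples; excluded",
                stacklevel=2,
            )
            continue
        resid = _residualize_on_year(
            grp["value"].to_numpy(dtype=float), grp["year_of_birth"].to_numpy()
        )
        grp = grp.copy()
        grp["y"] = inverse_normal(resid, offset=offset)
        out.append(grp)
    if not out:
        return raw.iloc[0:0].assign(y=pd.Series(dtype=float))
    return pd.concat(out).sort_index()


def sd_to_units(effect_sd: float, trait_sd: float) -> float:
    """Convert a standardized effect to physical units, rounded half-up to
    one decimal (e.g. -0.12 s.d. of a 6.6 cm trait -> -0.8 cm)."""
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    product = decimal.Decimal(repr(effect_sd)) * decimal.Decimal(repr(trait_sd))
    return float(product.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def units_to_sd(effect_units: float, trait_sd: float) -> float:
    """Inverse of :func:`sd_to_units` up to the reporting rounding."""
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    return effect_units / trait_sd
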