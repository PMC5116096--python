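"""Polygenic scoring and its explained variance.

A polygenic score is the weighted sum of per-sample effect-allele dosages
over a table of (variant, effect allele, weight in s.d. per allele); the
variance a score explains in a trait is the squared Pearson correlation
from a simple linear regression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import OrderedGenotypeMatrix

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["id", "allele", "weight"]


def score_samples(
    genotypes: OrderedGenotypeMatrix, weights: pd.DataFrame
) -> pd.Series:
    """Per-sample polygenic score Sum_j w_j * dosage(effect allele j).

    ``weights`` needs columns ``id, allele, weight``.  The effect allele
    must be the variant's ref or alt (ref flips the dosage to 2 - alt
    count); mismatching or unmatched weights are skipped and counted in
    the log.  Raises if no weight matches a genotyped variant.  Missing
    dosages contribute the cohort mean dosage of that variant (mean
    imputation keeps scores comparable across samples).
    """
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing columns {missing}")
    meta = genotypes.variants.set_index("id")
    add = genotypes.additive()
    score = np.zeros(genotypes.n_samples)
    used = skipped_absent = skipped_allele = 0
    for row in weights.itertuples():
        if row.id not in meta.index:
            skipped_absent += 1
            continue
        j = genotypes.variant_index(row.id)
        ref, alt = meta.loc[row.id, "ref"], meta.loc[row.id, "alt"]
        if row.allele == alt:
            dose = add[:, j]
        elif row.allele == ref:
            dose = 2.0 - add[:, j]
        else:
            skipped_allele += 1
            continue
        dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
        score += row.weight * dose
        used += 1
    if used == 0:
        raise ValueError("no weight matched a genotyped variant")
    if skipped_absent or skipped_allele:
        logger.info(
            "score_samples: %d weights used, %d absent, %d allele mismatches",
            used, skipped_absent, skipped_allele,
        )
    return pd.Series(score, index=genotypes.samples, name="pgs")


def variance_explained_by_score(score: pd.Series, y: pd.Series) -> float:
    """R^2 of the simple linear regression of the trait on the score
    (the squared Pearson correlation over paired non-missing samples)."""
    joined = pd.concat([score.rename("s"), y.rename("y")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired samples")
    if joined["s"].var() == 0:
        logger.warning("constant polygenic score; R^2 reported as 0")
        return 0.0
    r = np.corrcoef(joined["s"], joined["y"])[0, 1]
    return float(r * r)
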