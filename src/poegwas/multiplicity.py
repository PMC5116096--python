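"""Class-specific Bonferroni significance thresholds.

Genome-wide significance is controlled at family-wise level alpha by
splitting alpha across variant impact classes (high / moderate / low
predicted functional impact) and Bonferroni-correcting within each class:
t_c = alpha * w_c / N_c.  With equal weights this reproduces the classic
weighted-Bonferroni thresholds used for whole-genome scans (e.g. with
alpha = 0.05 and classes of 9,989 / 170,692 / 31,421,778 variants:
1.7e-6, 9.8e-8 and 5.3e-10).  A separate, much looser threshold (0.05 /
number of parent-of-origin signals) applies when asking whether the
opposite parental allele also carries an effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

IMPACT_CLASSES = ("high", "moderate", "low")


@dataclass
class ThresholdScheme:
    """Per-class Bonferroni thresholds t_c = alpha * w_c / N_c."""

    alpha: float
    counts: dict[str, int]
    weights: dict[str, float]
    thresholds: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        counts = {c: n for c, n in self.counts.items() if n > 0}
        if not counts:
            raise ValueError("no class with a positive variant count")
        weights = {c: self.weights.get(c, 0.0) for c in counts}
        total = sum(weights.values())
        if total <= 0:
            raise ValueError("class weights sum to zero")
        weights = {c: w / total for c, w in weights.items()}
        self.counts = counts
        self.weights = weights
        self.thresholds = {
            c: self.alpha * weights[c] / counts[c] for c in counts
        }

    def __getitem__(self, cls: str) -> float:
        return self.thresholds[cls]

    def most_stringent(self) -> float:
        return min(self.thresholds.values())


def class_thresholds(
    alpha: float,
    class_counts: dict[str, int],
    weights: dict[str, float] | None = None,
) -> ThresholdScheme:
    """Build a class-specific Bonferroni scheme.

    ``weights`` default to equal allocation across the classes with a
    positive count; they are normalized internally.  Classes with zero
    count are excluded from the allocation.
    """
    if weights is None:
        weights = {c: 1.0 for c, n in class_counts.items() if n > 0}
    return ThresholdScheme(alpha=alpha, counts=dict(class_counts), weights=dict(weights))


def call_significant(
    results: pd.DataFrame,
    scheme: ThresholdScheme,
    annotation: dict[str, str],
    p_column: str = "p_corrected",
) -> pd.DataFrame:
    """Flag genome-wide significant results.

    A result is significant iff its (corrected) P is strictly below the
    threshold of its variant's impact class.  Unannotated variants default
    to the most stringent class.  Adds ``impact_class``, ``threshold`` and
    ``significant`` columns.
    """
    out = results.copy()
    stringent = min(scheme.thresholds, key=scheme.thresholds.get)
    out["impact_class"] = [
        annotation.get(v, stringent) for v in out["variant"]
    ]
    unknown = ~out["impact_class"].isin(scheme.thresholds)
    out.loc[unknown, "impact_class"] = stringent
    out["threshold"] = out["impact_class"].map(scheme.thresholds)
    out["significant"] = out[p_column] < out["threshold"]
    out.loc[out[p_column].isna(), "significant"] = False
    return out


def opposite_parent_threshold(n_poo_signals: int) -> float:
    """Significance threshold for an effect of the opposite parental
    allele: 0.05 corrected for the number of genome-wide significant
    parent-of-origin signals (0.05/4 = 0.0125 for four signals)."""
    if n_poo_signals < 1:
        raise ValueError("need at least one parent-of-origin signal")
    return 0.05 / n_poo_signals
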