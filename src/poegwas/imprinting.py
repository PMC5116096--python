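"""Parent-of-origin specific analyses.

Three pieces distinguish true imprinting from other explanations of a
parent-of-origin signal: (1) Mendelian trio deduction assigns parental
origin to a child's alleles wherever it is logically forced; (2) the
non-transmitted-allele test regresses the child's trait on each of the
four parental alleles (transmitted / non-transmitted x paternal /
maternal) separately - imprinting loads only on a transmitted allele,
whereas a parental-genotype (e.g. in-utero) effect also shows on the
non-transmitted allele; (3) ordered-genotype summaries give the mean trait
per pat|mat genotype with confidence intervals widened by the square root
of the genomic correction factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CorrectionFactor
from .core import MISSING_PARENT, OrderedGenotypeMatrix, Pedigree

ORDERED_GENOTYPES = ("0|0", "1|0", "0|1", "1|1")  # pat|mat
ALLELE_COLUMNS = ("t_pat", "t_mat", "nt_pat", "nt_mat")
MIN_TRIOS = 30


def assign_parental_origin(
    child: tuple[int, int] | int,
    father: tuple[int, int] | int,
    mother: tuple[int, int] | int,
) -> tuple[int, int] | None:
    """Ordered (paternal, maternal) alleles of the child, or None.

    Genotypes are unordered allele counts (0/1/2) or allele pairs.  Origin
    is forced whenever the child is homozygous or at least one parent is
    homozygous; the triple-heterozygote is undecidable (None).  A
    Mendelian inconsistency raises ValueError.
    """
    c = _count(child)
    f = _count(father)
    m = _count(mother)
    if c == 0 or c == 2:
        allele = c // 2
        if (allele == 1 and (f == 0 or m == 0)) or (allele == 0 and (f == 2 or m == 2)):
            raise ValueError(
                f"Mendelian inconsistency: child {c}, father {f}, mother {m}"
            )
        return (allele, allele)
    # heterozygous child: an allele must come from each parent
    if f == 0 and m == 0:
        raise ValueError("Mendelian inconsistency: het child of two hom-ref parents")
    if f == 2 and m == 2:
        raise ValueError("Mendelian inconsistency: het child of two hom-alt parents")
    if f == 0:
        return (0, 1)
    if f == 2:
        return (1, 0)
    if m == 0:
        return (1, 0)
    if m == 2:
        return (0, 1)
    return None  # both parents heterozygous


def _count(g: tuple[int, int] | int) -> int:
    if isinstance(g, tuple):
        return int(g[0]) + int(g[1])
    return int(g)


def assign_trio_origins(
    additive: np.ndarray,
    samples: list[str],
    pedigree: Pedigree,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized trio deduction over an unordered genotype matrix.

    ``additive`` is (n_samples, n_variants) hard-call allele counts.
    Returns (paternal, maternal) dosage arrays with NaN where the origin is
    ambiguous, a parent is ungenotyped, or the trio is Mendelian-
    inconsistent.  Non-trio samples are all-NaN.
    """
    n, m = additive.shape
    pos = {s: i for i, s in enumerate(samples)}
    pat = np.full((n, m), np.nan)
    mat = np.full((n, m), np.nan)
    for r in pedigree.trios().itertuples():
        if r.iid not in pos or r.father not in pos or r.mother not in pos:
            continue
        ci, fi, mi = pos[r.iid], pos[r.father], pos[r.mother]
        c, f, mo = additive[ci], additive[fi], additive[mi]
        ok = ~(np.isnan(c) | np.isnan(f) | np.isnan(mo))
        hom = ok & ((c == 0) | (c == 2))
        consistent_hom = hom & ~(
            ((c == 2) & ((f == 0) | (mo == 0))) | ((c == 0) & ((f == 2) | (mo == 2)))
        )
        pat[ci, consistent_hom] = c[consistent_hom] / 2.0
        mat[ci, consistent_hom] = c[consistent_hom] / 2.0
        het = ok & (c == 1) & ~((f == 0) & (mo == 0)) & ~((f == 2) & (mo == 2))
        from_father = het & ((f == 2) | (mo == 0))
        from_mother = het & ((f == 0) | (mo == 2)) & ~from_father
        pat[ci, from_father] = 1.0
        mat[ci, from_father] = 0.0
        pat[ci, from_mother] = 0.0
        mat[ci, from_mother] = 1.0
    return pat, mat


def transmission_table(
    genotypes: OrderedGenotypeMatrix, pedigree: Pedigree, variant: str
) -> pd.DataFrame:
    """Transmitted and non-transmitted parental alleles at one variant.

    For every trio with ordered child dosages and genotyped parents:
    the transmitted paternal/maternal alleles are the child's ordered
    dosages, and each non-transmitted allele is the parent's allele count
    minus what was transmitted (so transmitted + non-transmitted
    reconstructs the parent's genotype).  Rows with any missing piece are
    dropped.
    """
    j = genotypes.variant_index(variant)
    pos = {s: i for i, s in enumerate(genotypes.samples)}
    add = genotypes.additive()
    rows = []
    for r in pedigree.trios().itertuples():
        if r.iid not in pos or r.father not in pos or r.mother not in pos:
            continue
        ci, fi, mi = pos[r.iid], pos[r.father], pos[r.mother]
        t_pat, t_mat = genotypes.paternal[ci, j], genotypes.maternal[ci, j]
        nt_pat = add[fi, j] - t_pat
        nt_mat = add[mi, j] - t_mat
        vals = (t_pat, t_mat, nt_pat, nt_mat)
        if any(np.isnan(v) for v in vals):
            continue
        if not (0 <= nt_pat <= 1 and 0 <= nt_mat <= 1):
            continue  # inconsistent trio
        rows.append((r.iid, *vals))
    return pd.DataFrame(rows, columns=["iid", *ALLELE_COLUMNS])


def nontransmitted_test(y: pd.Series, tt: pd.DataFrame) -> pd.DataFrame:
    """Simple linear regression of the child's standardized trait on each
    of the four allele columns separately.

    Returns one row per allele column with effect, se, P (two-sided t),
    n, and a low-power flag when fewer than 30 informative trios carry
    both the allele column and a phenotype.
    """
    merged = tt.merge(
        y.rename("y"), left_on="iid", right_index=True, how="inner"
    ).dropna(subset=["y"])
    rows = []
    for col in ALLELE_COLUMNS:
        sub = merged.dropna(subset=[col])
        n = len(sub)
        if n < 3 or np.var(sub[col]) == 0:
            rows.append((col, np.nan, np.nan, np.nan, n, True))
            continue
        fit = stats.linregress(sub[col], sub["y"])
        rows.append((col, fit.slope, fit.stderr, fit.pvalue, n, n < MIN_TRIOS))
    return pd.DataFrame(
        rows, columns=["allele", "effect", "se", "p", "n", "low_power"]
    )


def ordered_genotype_summary(
    y: pd.Series,
    genotypes: OrderedGenotypeMatrix,
    variant: str,
    cf: CorrectionFactor | float = 1.0,
    info_min: float = 0.8,
    sqrt_cf: bool = True,
) -> pd.DataFrame:
    """Mean standardized trait per ordered genotype with corrected CIs.

    Groups samples by hard-called pat|mat genotype and reports n, mean,
    s.e. of the mean and the 95% CI mean +/- 1.96 * se * sqrt(cf), where
    cf is the additive-model correction factor (set ``sqrt_cf=False`` to
    apply cf unrooted).  The variant must have imputation info above
    ``info_min``.  Empty groups appear with n=0 and no CI.
    """
    j = genotypes.variant_index(variant)
    info = float(genotypes.variants.loc[j, "info"])
    if not info > info_min:
        raise ValueError(
            f"variant {variant!r} has info {info:.3g} <= {info_min}"
        )
    factor = cf["additive"] if isinstance(cf, CorrectionFactor) else float(cf)
    widen = np.sqrt(factor) if sqrt_cf else factor
    yv = y.reindex(genotypes.samples).to_numpy(dtype=float)
    pat = np.round(genotypes.paternal[:, j])
    mat = np.round(genotypes.maternal[:, j])
    rows = []
    for label in ORDERED_GENOTYPES:
        pa, ma = (int(a) for a in label.split("|"))
        mask = (pat == pa) & (mat == ma) & ~np.isnan(yv)
        n = int(mask.sum())
        if n == 0:
            rows.append((label, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        vals = yv[mask]
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        half = 1.96 * se * widen if np.isfinite(se) else np.nan
        rows.append((label, n, mean, se, mean - half, mean + half))
    return pd.DataFrame(
        rows, columns=["genotype", "n", "mean", "se", "ci_low", "ci_high"]
    )
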