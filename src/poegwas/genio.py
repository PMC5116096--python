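"""Readers and writers for the formats the pipeline touches.

Conventions, fixed once at the boundary: VCF positions are 1-based and
converted to the internal 0-based half-open interval convention only for
region queries (BED stays 0-based half-open as on disk).  Phased genotypes
are read with the declared haplotype order (paternal|maternal by default);
pedigree-based trio deduction (:mod:`poegwas.imprinting`) can override a
file's phase convention downstream.  All text readers are
gzip-transparent.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING_PARENT, OrderedGenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["variant", "model", "effect_sd", "se", "chi2", "p", "p_corrected", "n"]
FAM_COLUMNS = ["fam", "iid", "father", "mother", "sex", "phe"]


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(path: str, paternal_first: bool = True) -> OrderedGenotypeMatrix:
    """Read a phased VCF into an ordered genotype matrix.

    The first allele of each phased GT is taken as paternal when
    ``paternal_first`` (the writer's convention); unphased or missing
    genotypes yield NaN in both parental slots at that site.  Multiallelic
    records are skipped with a warning.  Imputation info is taken from
    INFO/IMP_INFO (default 1.0).
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    meta_rows = []
    pat_rows, mat_rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {rec.CHROM}:{rec.POS}", stacklevel=2
            )
            continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        pat = np.full(len(samples), np.nan)
        mat = np.full(len(samples), np.nan)
        for i, g in enumerate(gts):
            if len(g) < 3:
                raise ValueError(
                    f"malformed GT for sample {samples[i]} at {rec.CHROM}:{rec.POS}"
                )
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0 or not phased:
                continue
            first, second = float(a0), float(a1)
            pat[i] = first if paternal_first else second
            mat[i] = second if paternal_first else first
        info = rec.INFO.get("IMP_INFO")
        meta_rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "info": float(info) if info is not None else 1.0,
            }
        )
        pat_rows.append(pat)
        mat_rows.append(mat)
    variants = pd.DataFrame(
        meta_rows, columns=["chrom", "pos", "id", "ref", "alt", "info"]
    )
    n, m = len(samples), len(variants)
    pat_arr = np.array(pat_rows).T if m else np.zeros((n, 0))
    mat_arr = np.array(mat_rows).T if m else np.zeros((n, 0))
    return OrderedGenotypeMatrix(samples, variants, pat_arr, mat_arr)


def write_phased_vcf(genotypes: OrderedGenotypeMatrix, path: str) -> None:
    """Write a VCF 4.2 with phased GTs, paternal allele first, and the
    per-variant imputation info in INFO/IMP_INFO."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=IMP_INFO,Number=1,Type=Float,'
            'Description="Imputation information score">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, v in genotypes.variants.iterrows():
            gts = []
            for i in range(genotypes.n_samples):
                p, m = genotypes.paternal[i, j], genotypes.maternal[i, j]
                if np.isnan(p) or np.isnan(m):
                    gts.append("./.")
                else:
                    gts.append(f"{int(round(p))}|{int(round(m))}")
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\tIMP_INFO={v['info']:g}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# FAM / pedigree


def read_pedigree(path: str) -> Pedigree:
    """Read a 6-column FAM file.  A parent id not present in the table is
    treated as unknown (founder) with a warning."""
    table = pd.read_csv(
        path, sep=r"\s+", header=None, names=FAM_COLUMNS, dtype=str
    )
    table["sex"] = table["sex"].astype(int)
    known = set(table["iid"])
    for col in ("father", "mother"):
        unknown = (~table[col].isin(known)) & (table[col] != MISSING_PARENT)
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} {col} id(s) absent from FAM; "
                "treated as founders",
                stacklevel=2,
            )
            table.loc[unknown, col] = MISSING_PARENT
    return Pedigree(table[["fam", "iid", "father", "mother", "sex"]])


def write_pedigree(pedigree: Pedigree, path: str) -> None:
    out = pedigree.table[["fam", "iid", "father", "mother", "sex"]].copy()
    out["phe"] = 0
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED regions


@dataclass
class RegionSet:
    """Labelled genomic intervals, 0-based half-open as in BED."""

    intervals: pd.DataFrame  # columns chrom, start, end
    label: str = ""

    def __post_init__(self) -> None:
        iv = self.intervals
        if not {"chrom", "start", "end"}.issubset(iv.columns):
            raise ValueError("intervals need chrom, start, end columns")
        if (iv["start"] >= iv["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.intervals = iv.reset_index(drop=True)

    def expand(self, flank: int) -> "RegionSet":
        """Widen every interval by ``flank`` bp on both sides, flooring at 0."""
        iv = self.intervals.copy()
        iv["start"] = (iv["start"] - flank).clip(lower=0)
        iv["end"] = iv["end"] + flank
        return RegionSet(iv, label=self.label)

    def merge(self) -> "RegionSet":
        """Merge overlapping or adjacent intervals per chromosome."""
        rows = []
        for chrom, grp in self.intervals.groupby("chrom"):
            grp = grp.sort_values("start")
            cur_s = cur_e = None
            for r in grp.itertuples():
                if cur_s is None:
                    cur_s, cur_e = r.start, r.end
                elif r.start <= cur_e:
                    cur_e = max(cur_e, r.end)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = r.start, r.end
            rows.append((chrom, cur_s, cur_e))
        return RegionSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]), label=self.label
        )

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based (VCF-style) coordinate."""
        p = pos_1based - 1  # to 0-based
        iv = self.intervals
        hit = (iv["chrom"].astype(str) == str(chrom)) & (iv["start"] <= p) & (p < iv["end"])
        return bool(hit.any())


def read_regions(path: str, label: str = "") -> RegionSet:
    table = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
        comment="#",
    )
    return RegionSet(table, label=label)


def write_regions(regions: RegionSet, path: str) -> None:
    regions.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# annotation, phenotypes, results


def read_annotation(path: str) -> dict[str, str]:
    """Variant id -> impact class (high/moderate/low) from a 2-column TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "impact"}.issubset(table.columns):
        raise ValueError("annotation TSV needs columns 'id' and 'impact'")
    return dict(zip(table["id"], table["impact"]))


def write_annotation(annotation: dict[str, str], path: str) -> None:
    pd.DataFrame(
        {"id": list(annotation), "impact": list(annotation.values())}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(phenotypes: pd.DataFrame, path: str) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: str) -> None:
    """Association results as TSV with the fixed column contract
    (variant, model, effect_sd, se, chi2, p, p_corrected, n).  An empty
    collection yields a header-only file."""
    out = results.rename(columns={"beta": "effect_sd"}).copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return table.rename(columns={"effect_sd": "beta"})
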