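"""Core in-memory containers shared across the pipeline.

Two containers carry nearly all state: :class:`Pedigree` (who descends from
whom, plus sex) and :class:`OrderedGenotypeMatrix` (per-sample paternal and
maternal allele dosages plus per-variant metadata).  Phenotypes travel as
plain :class:`pandas.DataFrame` objects with a fixed column contract (see
:mod:`poegwas.phenotype`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = 1
FEMALE = 2
MISSING_PARENT = "0"

#: columns of a pedigree frame, in FAM order minus the phenotype column
PED_COLUMNS = ["fam", "iid", "father", "mother", "sex"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts)."""


@dataclass
class Pedigree:
    """A pedigree: one row per individual with father, mother and sex.

    Parent IDs equal to ``"0"`` denote unknown parents (founders).  The
    table is validated on construction: every named parent must have the
    right sex if present, and the ancestry graph must be acyclic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PED_COLUMNS if c not in t.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns {missing}")
        t = t.astype({"iid": str, "father": str, "mother": str})
        if t["iid"].duplicated().any():
            dup = t.loc[t["iid"].duplicated(), "iid"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        self.table = t.reset_index(drop=True)
        sex = dict(zip(t["iid"], t["sex"]))
        for col, want in (("father", MALE), ("mother", FEMALE)):
            named = t.loc[t[col] != MISSING_PARENT, col]
            bad = [p for p in named if sex.get(p, want) != want]
            if bad:
                raise PedigreeError(f"{col} {bad[0]!r} has inconsistent sex")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order = self.topological_order()  # raises on cycle
        assert len(order) == len(self.table)

    # -- accessors ---------------------------------------------------------
    @property
    def iids(self) -> list[str]:
        return list(self.table["iid"])

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        row = self.table.set_index("iid").loc[iid]
        f = None if row["father"] == MISSING_PARENT else row["father"]
        m = None if row["mother"] == MISSING_PARENT else row["mother"]
        return f, m

    def is_founder(self) -> pd.Series:
        """Boolean mask (indexed like ``table``) of individuals with no
        known parent in the table."""
        known = set(self.table["iid"])
        f_in = self.table["father"].isin(known)
        m_in = self.table["mother"].isin(known)
        return ~(f_in | m_in)

    def founders(self) -> list[str]:
        return list(self.table.loc[self.is_founder(), "iid"])

    def trios(self) -> pd.DataFrame:
        """Children whose both parents are present in the table."""
        known = set(self.table["iid"])
        m = self.table["father"].isin(known) & self.table["mother"].isin(known)
        return self.table.loc[m, ["iid", "father", "mother"]].reset_index(drop=True)

    def topological_order(self) -> list[str]:
        """Individual ids ordered so that parents precede children.

        Raises :class:`PedigreeError` naming a cycle member if the
        ancestry graph is cyclic.
        """
        known = set(self.table["iid"])
        parents = {
            r.iid: [p for p in (r.father, r.mother) if p in known]
            for r in self.table.itertuples()
        }
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        for root in parents:
            if root in state:
                continue
            stack = [(root, iter(parents[root]))]
            state[root] = 0
            while stack:
                node, it = stack[-1]
                for p in it:
                    if state.get(p) == 0:
                        raise PedigreeError(f"pedigree cycle through {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(parents[p])))
                        break
                else:
                    state[node] = 1
                    order.append(node)
                    stack.pop()
        return order

    def __len__(self) -> int:
        return len(self.table)


#: columns of the variant metadata frame
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "info"]


@dataclass
class OrderedGenotypeMatrix:
    """Phased dosages split by parental origin.

    ``paternal`` and ``maternal`` are ``(n_samples, n_variants)`` float
    arrays of per-haplotype minor/alt allele dosages in [0, 1]; ``NaN``
    marks a haplotype whose parental origin (or genotype) is unknown.
    ``variants`` carries per-variant metadata including the imputation
    ``info`` score in [0, 1].
    """

    samples: list[str]
    variants: pd.DataFrame
    paternal: np.ndarray
    maternal: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.variants)
        for name in ("paternal", "maternal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, m):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n, m)}"
                )
            setattr(self, name, arr)
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants frame missing columns {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def additive(self) -> np.ndarray:
        """Unordered expected alt-allele count in [0, 2] (NaN if either
        haplotype is missing)."""
        return self.paternal + self.maternal

    def allele_frequency(self) -> np.ndarray:
        """Per-variant alt allele frequency from non-missing additive dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.additive(), axis=0) / 2.0

    def variant_index(self, vid: str) -> int:
        idx = self.variants.index[self.variants["id"] == vid]
        if len(idx) == 0:
            raise KeyError(f"variant {vid!r} not in matrix")
        return int(idx[0])

    def subset_variants(self, mask: np.ndarray) -> "OrderedGenotypeMatrix":
        mask = np.asarray(mask)
        return OrderedGenotypeMatrix(
            samples=self.samples,
            variants=self.variants.loc[mask].reset_index(drop=True),
            paternal=self.paternal[:, mask],
            maternal=self.maternal[:, mask],
        )

    def subset_samples(self, iids: list[str]) -> "OrderedGenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = np.array([pos[i] for i in iids], dtype=int)
        return OrderedGenotypeMatrix(
            samples=list(iids),
            variants=self.variants,
            paternal=self.paternal[rows],
            maternal=self.maternal[rows],
        )
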