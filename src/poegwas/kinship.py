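"""Pedigree kinship and cluster partitioning.

The association model's covariance is parameterized by K = 2*Phi, where
Phi is the pedigree kinship coefficient matrix computed by the classic
recursive (tabular) method.  Kinship is exactly zero between individuals
with no common ancestor, so Phi is block-diagonal over the connected
components of the pedigree graph and is stored that way; a cohort of
unrelated samples costs O(n), not O(n^2).  Because inverting a huge K
block would be O(n^3), oversized components are additionally split into
family clusters; the GLS likelihood then factorizes over clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import Pedigree

logger = logging.getLogger(__name__)

DEFAULT_MAX_CLUSTER = 2000
PSD_JITTER = 1e-8


@dataclass
class KinshipMatrix:
    """Kinship coefficients Phi, block-diagonal over pedigree components.

    ``blocks`` is a list of ``(iids, phi)`` pairs; pairs of individuals in
    different blocks have kinship exactly 0.  ``phi[i, j]`` is the
    probability that one allele drawn from i and one from j are identical
    by descent; ``K = 2 * phi`` scales the phenotypic covariance, with
    diagonal 1 + inbreeding >= 1.
    """

    samples: list[str]
    blocks: list[tuple[list[str], np.ndarray]]

    def __post_init__(self) -> None:
        self._block_of: dict[str, tuple[int, int]] = {}
        for bi, (iids, phi) in enumerate(self.blocks):
            if phi.shape != (len(iids), len(iids)):
                raise ValueError("phi block shape mismatch")
            for i, iid in enumerate(iids):
                self._block_of[iid] = (bi, i)
        missing = [s for s in self.samples if s not in self._block_of]
        if missing:
            raise ValueError(f"samples missing from kinship blocks: {missing[:5]}")

    def is_identity(self) -> bool:
        """True when K = I (all samples unrelated and non-inbred)."""
        return all(
            phi.shape == (1, 1) and phi[0, 0] == 0.5 for _, phi in self.blocks
        )

    def phi_pair(self, a: str, b: str) -> float:
        ba, ia = self._block_of[a]
        bb, ib = self._block_of[b]
        if ba != bb:
            return 0.0
        return float(self.blocks[ba][1][ia, ib])

    def submatrix(self, iids: list[str]) -> np.ndarray:
        """Dense K = 2*Phi restricted to ``iids`` (cross-block pairs 0)."""
        n = len(iids)
        out = np.zeros((n, n))
        where = [self._block_of[i] for i in iids]
        for r in range(n):
            br, ir = where[r]
            phi = self.blocks[br][1]
            for c in range(r, n):
                bc, ic = where[c]
                if br == bc:
                    out[r, c] = out[c, r] = 2.0 * phi[ir, ic]
        return out

    def to_dense(self) -> np.ndarray:
        """Dense K for the full sample set (small cohorts only)."""
        return self.submatrix(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.samples, columns=self.samples)


@dataclass
class ClusterPartition:
    """Disjoint sample clusters covering the cohort; pedigree edges cut to
    enforce the size cap are recorded in ``cut_edges``."""

    clusters: list[list[str]]
    cut_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def max_size(self) -> int:
        return max((len(c) for c in self.clusters), default=0)

    def __iter__(self):
        return iter(self.clusters)


def _pedigree_graph(pedigree: Pedigree) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(pedigree.iids)
    known = set(pedigree.iids)
    for r in pedigree.table.itertuples():
        for p in (r.father, r.mother):
            if p in known:
                g.add_edge(r.iid, p)
    return g


def pedigree_kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Recursive pedigree kinship, per connected pedigree component.

    Founders are unrelated and non-inbred.  Processing parents before
    children, phi_jj = (1 + phi_fm)/2 and phi_ij = (phi_i,father(j) +
    phi_i,mother(j))/2 for any earlier individual i.  Parent-offspring and
    full-sib pairs get phi = 1/4, half sibs 1/8, etc.
    """
    order = pedigree.topological_order()  # raises PedigreeError on a cycle
    rank = {iid: i for i, iid in enumerate(order)}
    parent_of = {r.iid: (r.father, r.mother) for r in pedigree.table.itertuples()}
    graph = _pedigree_graph(pedigree)

    blocks: list[tuple[list[str], np.ndarray]] = []
    for comp in nx.connected_components(graph):
        iids = sorted(comp, key=rank.__getitem__)  # parents before children
        n = len(iids)
        pos = {iid: i for i, iid in enumerate(iids)}
        phi = np.zeros((n, n))
        for j, iid in enumerate(iids):
            f, m = parent_of[iid]
            fi, mi = pos.get(f), pos.get(m)
            phi_fm = phi[fi, mi] if fi is not None and mi is not None else 0.0
            phi[j, j] = 0.5 * (1.0 + phi_fm)
            for i in range(j):
                val = 0.0
                if fi is not None:
                    val += 0.5 * phi[i, fi]
                if mi is not None:
                    val += 0.5 * phi[i, mi]
                phi[i, j] = phi[j, i] = val
        blocks.append((iids, phi))
    return KinshipMatrix(samples=pedigree.iids, blocks=blocks)


def partition_clusters(
    pedigree: Pedigree, max_size: int = DEFAULT_MAX_CLUSTER
) -> ClusterPartition:
    """Partition samples into pedigree-connected clusters of size <= max_size.

    Connected components of the parent-child graph are kept whole when they
    fit; larger components are split by repeated balanced bisection
    (Kernighan-Lin), cutting as few parent-child edges as the greedy
    heuristic finds.  Cut edges are logged and reported.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    graph = _pedigree_graph(pedigree)
    clusters: list[list[str]] = []
    cut: list[tuple[str, str]] = []

    stack = [set(c) for c in nx.connected_components(graph)]
    while stack:
        comp = stack.pop()
        if len(comp) <= max_size or len(comp) == 1:
            clusters.append(sorted(comp))
            continue
        sub = graph.subgraph(comp)
        a, b = nx.algorithms.community.kernighan_lin_bisection(sub, seed=0)
        edges = [(u, v) for u, v in sub.edges if (u in a) != (v in a)]
        cut.extend(edges)
        stack.extend([set(a), set(b)])

    if cut:
        logger.info("partition_clusters cut %d pedigree edges", len(cut))
    order = {iid: i for i, iid in enumerate(pedigree.iids)}
    clusters.sort(key=lambda c: min(order[i] for i in c))
    return ClusterPartition(clusters=clusters, cut_edges=cut)


def cluster_cholesky(
    kin: KinshipMatrix, partition: ClusterPartition, jitter: float = PSD_JITTER
) -> dict[int, tuple[list[str], np.ndarray]]:
    """Lower Cholesky factor of K restricted to each cluster (with a jitter
    retry for near-singular blocks).  Keyed by cluster index."""
    out: dict[int, tuple[list[str], np.ndarray]] = {}
    for ci, iids in enumerate(partition):
        k = kin.submatrix(iids)
        try:
            chol = np.linalg.cholesky(k)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(k + jitter * np.eye(len(iids)))
        out[ci] = (iids, chol)
    return out
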