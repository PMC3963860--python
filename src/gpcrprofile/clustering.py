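"""Agglomerative hierarchical clustering of cell types on GPCR signatures.

The clustering used in the source study was run in closed-source software
with unstated settings, so the whole chain is implemented here from first
principles and kept configurable: feature vectors are the negated aligned
Ct values (the log2-abundance scale, with silent genes contributing the
negated sentinel), pairwise dissimilarity defaults to 1 - Pearson
correlation, and trees are built by average linkage (UPGMA), where the
distance between two clusters is the mean of all cross-cluster leaf-pair
dissimilarities.  Ties are broken deterministically on the lexicographically
smallest label pair, and leaves are sorted internally so the result does not
depend on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import ExpressionProfile, filter_expressed

__all__ = [
    "ClusteringError",
    "DegenerateProfileError",
    "DistanceMatrix",
    "Dendrogram",
    "expression_distance",
    "agglomerate",
    "cut_tree",
]


class ClusteringError(ValueError):
    pass


class DegenerateProfileError(ClusteringError):
    """A zero-variance feature vector under a correlation metric."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities between labelled items."""

    labels: list[str]
    values: np.ndarray
    metric: str = "one_minus_pearson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ClusteringError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ClusteringError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ClusteringError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ClusteringError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ClusteringError("negative distances")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    Leaves are numbered 0..n-1 in sorted-label order; the cluster created by
    merge ``i`` has id ``n + i``.  ``merges`` holds (left id, right id,
    height, size) with non-decreasing heights for average linkage.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def to_linkage(self) -> np.ndarray:
        """The merge history as a SciPy-style linkage array."""
        return np.array([[l, r, h, s] for l, r, h, s in self.merges], dtype=float)

    def _members(self) -> dict[int, frozenset[str]]:
        members = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        for i, (l, r, _h, _s) in enumerate(self.merges):
            members[self.n_leaves + i] = members[l] | members[r]
        return members

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: lab for i, lab in enumerate(self.labels)}
        for i, (l, r, h, _s) in enumerate(self.merges):
            nid = n + i
            bl_l, bl_r = h - height[l], h - height[r]
            node[nid] = f"({node[l]}:{bl_l:.6g},{node[r]}:{bl_r:.6g})"
            height[nid] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"


def expression_distance(
    profiles: ExpressionProfile,
    genes: frozenset[str] | list[str] | None = None,
    metric: str = "one_minus_pearson",
    scale: str = "neg_ct",
) -> DistanceMatrix:
    """Pairwise dissimilarity between cell types over a gene set.

    ``genes`` defaults to the union set of the expression-cutoff filter.
    Feature vectors are -Ct per cell type (``scale="neg_ct"``); silent genes
    contribute the negated sentinel Ct, so shared absence is itself signal.
    """
    if genes is None:
        genes = filter_expressed(profiles).union
    genes = sorted(genes)
    if len(genes) < 2:
        raise ClusteringError("need at least two genes")
    cells = sorted(profiles.cell_types)
    if len(cells) < 2:
        raise ClusteringError("need at least two cell types")

    ct = profiles.ct_matrix().loc[genes, cells]
    if ct.isna().any().any():
        raise ClusteringError("missing Ct values for requested genes")
    if scale == "neg_ct":
        feats = -ct.to_numpy(dtype=float).T  # cells x genes
    elif scale == "units":
        feats = profiles.units_matrix().loc[genes, cells].to_numpy(dtype=float).T
    else:
        raise ClusteringError(f"unknown scale {scale!r}")

    n = len(cells)
    dist = np.zeros((n, n))
    if metric == "one_minus_pearson":
        sd = feats.std(axis=1)
        flat = [cells[i] for i in np.nonzero(sd == 0)[0]]
        if flat:
            raise DegenerateProfileError(f"zero-variance profiles: {flat}")
        corr = np.corrcoef(feats)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    elif metric == "euclidean":
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.linalg.norm(feats[i] - feats[j]))
                dist[i, j] = dist[j, i] = d
    else:
        raise ClusteringError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels=cells, values=dist, metric=metric)


def agglomerate(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Build a dendrogram by sequential agglomeration.

    Average linkage scores a candidate merge by the unweighted mean of all
    original leaf-pair distances across the two clusters (UPGMA); single and
    complete linkage use the min and max.  Ties are broken by the smallest
    (lexicographically) pair of cluster label sets, making the merge order
    deterministic and independent of input order.
    """
    if linkage not in {"average", "single", "complete"}:
        raise ClusteringError(f"unknown linkage {linkage!r}")
    order = np.argsort(np.array(dist.labels, dtype=object))
    labels = [dist.labels[i] for i in order]
    base = dist.values[np.ix_(order, order)]
    n = len(labels)
    if n < 2:
        raise ClusteringError("need at least two leaves")

    # active cluster id -> (leaf index set, sort key)
    active: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    key = {i: (labels[i],) for i in range(n)}
    dend = Dendrogram(labels=labels)
    next_id = n
    last_height = -np.inf

    def cluster_distance(a: frozenset[int], b: frozenset[int]) -> float:
        block = base[np.ix_(sorted(a), sorted(b))]
        if linkage == "average":
            return float(block.mean())
        if linkage == "single":
            return float(block.min())
        return float(block.max())

    while len(active) > 1:
        best: tuple[float, tuple, tuple, int, int] | None = None
        for i, j in ((i, j) for i in active for j in active if i < j):
            d = cluster_distance(active[i], active[j])
            ki, kj = sorted((key[i], key[j]))
            cand = (d, ki, kj, i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        assert best is not None
        d, _ki, _kj, i, j = best
        merged = active[i] | active[j]
        if linkage == "average" and d < last_height - 1e-9:
            raise ClusteringError("non-monotone merge heights under average linkage")
        last_height = max(last_height, d)
        dend.merges.append((i, j, d, len(merged)))
        del active[i], active[j]
        active[next_id] = merged
        key[next_id] = min(key[i], key[j])
        next_id += 1
    return dend


def cut_tree(dendrogram: Dendrogram, k: int) -> list[frozenset[str]]:
    """Partition the leaves into ``k`` clusters by undoing the last merges."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} out of range 1..{n}")
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (l, r, _h, _s) in enumerate(dendrogram.merges[: n - k]):
        nid = n + i
        parent[find(l)] = nid
        parent[find(r)] = nid

    clusters: dict[int, set[str]] = {}
    for leaf in range(n):
        clusters.setdefault(find(leaf), set()).add(dendrogram.labels[leaf])
    return sorted((frozenset(c) for c in clusters.values()), key=lambda c: sorted(c)[0])
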