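"""Sample-sample distances, agglomerative clustering, and tree cutting.

Patients are clustered on their full expression profiles over a grid of
distance metrics (Manhattan, Canberra, binary, Minkowski, Euclidean) and
linkage rules (Ward D, Ward D2, complete). The two Ward variants follow
the convention of classic statistical environments: Ward D applies the
Lance-Williams Ward update to the supplied distances as-is, Ward D2
applies it to squared distances and reports square-root merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix

METRICS = ("manhattan", "canberra", "binary", "minkowski", "euclidean")
LINKAGES = ("ward_d", "ward_d2", "complete")

#: Default grid: the binary distance is degenerate on scaled/centred data
#: (values are never exactly zero, so every pairwise distance collapses to
#: 0 and the dendrogram is arbitrary), so the default search runs the 12
#: informative metric x linkage combinations. Binary stays selectable.
DEFAULT_GRID_METRICS = ("manhattan", "canberra", "minkowski", "euclidean")


@dataclass(frozen=True)
class DistanceSpec:
    metric: str
    minkowski_power: float = 2.0
    canberra_variant: str = "classic"  # or "signed_sum" (|x+y| denominator)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if not (np.isfinite(self.minkowski_power) and self.minkowski_power > 0):
            raise ValueError("minkowski_power must be finite and > 0")
        if self.canberra_variant not in ("classic", "signed_sum"):
            raise ValueError(f"unknown canberra_variant {self.canberra_variant!r}")


@dataclass(frozen=True)
class LinkageSpec:
    method: str

    def __post_init__(self) -> None:
        if self.method not in LINKAGES:
            raise ValueError(f"method must be one of {LINKAGES}, got {self.method!r}")


@dataclass
class Dendrogram:
    """Result of agglomerative clustering.

    ``merges`` lists (left, right, height) where node ids < ``n_leaves``
    are leaves and id ``n_leaves + i`` is the cluster created by merge
    ``i``. ``leaf_order`` is the depth-first leaf ordering used for
    deterministic cluster labelling.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    leaf_ids: list[str]
    leaf_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")
        if not self.leaf_order:
            self.leaf_order = self._compute_leaf_order()

    def _compute_leaf_order(self) -> list[int]:
        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            left, right, _ = self.merges[node - self.n_leaves]
            return walk(left) + walk(right)

        return walk(2 * self.n_leaves - 2) if self.n_leaves > 1 else [0]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


@dataclass
class ClusterAssignment:
    """Sample id -> cluster label (1..k), labels ordered by first
    appearance along the dendrogram leaf order."""

    labels: dict[str, int]
    k: int

    def members(self, label: int) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == label]

    def label_vector(self, sample_ids=None) -> np.ndarray:
        ids = sample_ids if sample_ids is not None else list(self.labels)
        return np.array([self.labels[s] for s in ids])


def compute_distance(matrix: ExpressionMatrix, spec: DistanceSpec) -> pd.DataFrame:
    """Pairwise sample distances on a scaled expression matrix."""
    if matrix.unit != "scaled":
        raise ValueError("distances are computed on scaled matrices; run preprocess first")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    X = np.asarray(matrix.values, dtype=float).T  # samples x features
    bad = ~np.isfinite(np.asarray(matrix.values, dtype=float))
    if bad.any():
        fid = matrix.feature_ids[int(np.where(bad.any(axis=1))[0][0])]
        raise ValueError(f"non-finite expression values in feature {fid!r}")
    if spec.metric == "manhattan":
        d = pdist(X, "cityblock")
    elif spec.metric == "euclidean":
        d = pdist(X, "euclidean")
    elif spec.metric == "minkowski":
        d = pdist(X, "minkowski", p=spec.minkowski_power)
    elif spec.metric == "canberra":
        if spec.canberra_variant == "classic":
            d = pdist(X, "canberra")
        else:
            d = pdist(X, lambda u, v: _canberra_signed_sum(u, v))
    else:  # binary: mismatch fraction over positions where either is nonzero
        d = pdist(X != 0, "jaccard")
    return pd.DataFrame(squareform(d), index=matrix.sample_ids, columns=matrix.sample_ids)


def _canberra_signed_sum(u: np.ndarray, v: np.ndarray) -> float:
    denom = np.abs(u + v)
    num = np.abs(u - v)
    mask = denom > 0
    return float(np.sum(num[mask] / denom[mask]))


def agglomerate(dist: pd.DataFrame, linkage: LinkageSpec) -> Dendrogram:
    """Bottom-up clustering by Lance-Williams updates.

    Ties in the minimum working distance are broken by the smallest
    (left, right) node-id pair, so the tree is deterministic.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    squared = linkage.method == "ward_d2"
    W = D.astype(float).copy() ** (2 if squared else 1)
    np.fill_diagonal(W, np.inf)

    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> cluster size
    pos: dict[int, int] = {i: i for i in range(n)}  # node id -> row in W
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        ids = sorted(active)
        best = None
        for ai, i in enumerate(ids):
            for j in ids[ai + 1 :]:
                w = W[pos[i], pos[j]]
                if best is None or w < best[0]:  # exact ties keep smallest (i, j)
                    best = (w, i, j)
        w, i, j = best
        height = float(np.sqrt(w)) if squared else float(w)
        merges.append((i, j, height))
        ni, nj = active[i], active[j]
        pi, pj = pos[i], pos[j]
        # Lance-Williams update of every other active cluster's distance
        for k in active:
            if k in (i, j):
                continue
            pk = pos[k]
            dki, dkj = W[pk, pi], W[pk, pj]
            if linkage.method == "complete":
                new = max(dki, dkj)
            else:  # ward coefficients
                nk = active[k]
                tot = ni + nj + nk
                new = ((ni + nk) * dki + (nj + nk) * dkj - nk * w) / tot
            W[pk, pi] = W[pi, pk] = new
        del active[i], active[j]
        active[next_id] = ni + nj
        pos[next_id] = pi
        del pos[i], pos[j]
        next_id += 1

    return Dendrogram(merges=merges, n_leaves=n, leaf_ids=list(dist.index))


def cut_dendrogram(dendro: Dendrogram, k: int) -> ClusterAssignment:
    """Undo the last k-1 merges; label clusters 1..k by leaf order."""
    n = dendro.n_leaves
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _) in enumerate(dendro.merges[: n - k]):
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node

    label_of_root: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in dendro.leaf_order:
        root = find(leaf)
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        labels[dendro.leaf_ids[leaf]] = label_of_root[root]
    return ClusterAssignment(labels=labels, k=k)
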