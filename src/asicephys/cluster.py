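"""Unsupervised cell taxonomy: uniformity filtering, min-max normalization,
and Ward's-method agglomerative clustering on squared Euclidean distances.

The procedure mirrors classical interneuron-classification practice:

1. drop features whose distribution over the cohort is consistent with a
   uniform law on its observed range (they carry no cluster structure);
2. min-max normalize the retained features into [0, 1];
3. agglomerate greedily, at each step merging the pair of clusters whose
   fusion minimally increases the total within-cluster error sum of
   squares (ESS) — Ward's criterion;
4. cut the dendrogram at an analyst-chosen number of clusters k.

Merge heights are the ESS increases themselves (not their square roots),
which makes the dendrogram directly comparable to an exhaustive
ESS-increase oracle.  Ties are broken toward the lexicographically
smallest (oldest) pair of cluster indices, so runs are deterministic
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

__all__ = [
    "Dendrogram",
    "UniformityFilter",
    "RangeNormalizer",
    "WardClusterer",
    "uniformity_filter",
    "minmax_normalize",
    "ward_cluster",
    "assign_labels",
]


@dataclass
class Dendrogram:
    """Merge table of an agglomeration over n points.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height,
    merged_size).  Original points are clusters 0..n-1; the i-th merge
    creates cluster n+i.  Heights are ESS increases and non-decreasing.
    """

    merges: np.ndarray
    n_points: int

    def __post_init__(self):
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (self.n_points - 1, 4):
            raise ValueError("expected n-1 merges with 4 fields each")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise AssertionError("merge heights must be non-decreasing (Ward monotonicity)")
        if self.merges[-1, 3] != self.n_points:
            raise ValueError("final merge must contain all points")

    def cut(self, k: int) -> np.ndarray:
        """Labels for a k-cluster cut; clusters numbered 1..k by decreasing size."""
        n = self.n_points
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = np.arange(n + len(self.merges))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, (a, b, _, _) in enumerate(self.merges[: n - k]):
            new = n + i
            parent[find(int(a))] = new
            parent[find(int(b))] = new
        roots = np.array([find(i) for i in range(n)])
        uniq, first_seen = np.unique(roots, return_index=True)
        # order clusters by decreasing size, ties by first appearance
        sizes = np.array([(roots == u).sum() for u in uniq])
        order = sorted(range(len(uniq)), key=lambda j: (-sizes[j], first_seen[j]))
        label_of = {uniq[j]: rank + 1 for rank, j in enumerate(order)}
        return np.array([label_of[r] for r in roots], dtype=int)


class UniformityFilter(BaseEstimator, TransformerMixin):
    """Drop features whose cohort distribution looks uniform.

    Each column is rescaled to its observed [min, max] range and tested
    against the standard uniform law with the exact one-sample
    Kolmogorov–Smirnov test; columns that fail to reject at ``alpha``
    are dropped, as are zero-range (constant) columns.  Estimating the
    range from the data makes the test conservative at the edges; this
    bias is accepted and documented.

    Fitted attributes: ``retained_`` (column names or indices),
    ``report_`` (per-feature statistic, p-value, decision).
    """

    def __init__(self, alpha: float = 0.05, min_cells: int = 8):
        self.alpha = alpha
        self.min_cells = min_cells

    def fit(self, X, y=None):
        X = _as_frame(X)
        if len(X) < self.min_cells:
            raise ValueError(f"need >= {self.min_cells} cells, got {len(X)}")
        report = []
        retained = []
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi - lo <= 0:
                report.append((col, np.nan, np.nan, "dropped: degenerate range"))
                continue
            u = (x - lo) / (hi - lo)
            stat, p = sps.kstest(u, "uniform")
            if p < self.alpha:
                retained.append(col)
                report.append((col, float(stat), float(p), "retained: nonuniform"))
            else:
                report.append((col, float(stat), float(p), "dropped: uniform"))
        if not retained:
            raise ValueError(
                "all features dropped by the uniformity filter; "
                "select features manually or disable the filter"
            )
        self.retained_ = retained
        self.report_ = pd.DataFrame(report, columns=["feature", "ks_statistic", "p_value", "decision"])
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X[self.retained_]


class RangeNormalizer(BaseEstimator, TransformerMixin):
    """Min-max normalization to [0, 1] per feature (x - min)/(max - min)."""

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        if np.any((self.max_ - self.min_).to_numpy() <= 0):
            bad = list(self.min_.index[(self.max_ - self.min_) <= 0])
            raise ValueError(f"zero-range columns {bad}: filter them before normalizing")
        return self

    def transform(self, X):
        X = _as_frame(X)
        return (X - self.min_) / (self.max_ - self.min_)


class WardClusterer(BaseEstimator, ClusterMixin):
    """Ward's-method agglomeration with ESS-increase heights.

    At each step the pair of clusters whose merge minimally increases
    the total within-cluster error sum of squares is fused; for clusters
    A, B with centroids c_A, c_B that increase is

        d(A, B) = |A||B| / (|A| + |B|) * ||c_A - c_B||^2 .

    Equal-cost candidates are resolved toward the lexicographically
    smallest (oldest) pair of cluster indices.  With ``n_clusters`` set,
    ``fit`` also cuts the tree and exposes ``labels_``.

    Fitted attributes: ``tree_`` (:class:`Dendrogram`), ``labels_``.
    """

    def __init__(self, n_clusters: Optional[int] = None):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = _as_frame(X)
        mat = X.to_numpy(dtype=float)
        if np.isnan(mat).any():
            raise ValueError("missing values: exclude incomplete cells before clustering")
        n = mat.shape[0]
        if n < 2:
            raise ValueError("need at least 2 points")
        # active clusters: id -> (centroid, size); ids 0..n-1 then n, n+1, ...
        centroids = {i: mat[i].copy() for i in range(n)}
        sizes = {i: 1 for i in range(n)}
        merges = []
        next_id = n
        for _ in range(n - 1):
            ids = sorted(centroids)
            cmat = np.array([centroids[i] for i in ids])
            svec = np.array([sizes[i] for i in ids], dtype=float)
            diff = cmat[:, None, :] - cmat[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            w = np.outer(svec, svec) / (svec[:, None] + svec[None, :]) * d2
            iu, ju = np.triu_indices(len(ids), 1)
            costs = w[iu, ju]
            cmin = float(costs.min())
            ties = np.nonzero(costs == cmin)[0]
            # lexicographically smallest (oldest) pair among equal-cost merges
            ai, bi = min((iu[t], ju[t]) for t in ties)
            cost, a, b = cmin, ids[ai], ids[bi]
            na, nb = sizes[a], sizes[b]
            centroids[next_id] = (na * centroids[a] + nb * centroids[b]) / (na + nb)
            sizes[next_id] = na + nb
            del centroids[a], centroids[b], sizes[a], sizes[b]
            merges.append((a, b, cost, na + nb))
            next_id += 1
        self.tree_ = Dendrogram(np.array(merges, dtype=float), n)
        if self.n_clusters is not None:
            self.labels_ = self.tree_.cut(self.n_clusters)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# --------------------------------------------------------------------------
# thin functional surface


def uniformity_filter(matrix, alpha: float = 0.05):
    """Retain the features that reject uniformity; returns (matrix, report)."""
    f = UniformityFilter(alpha=alpha).fit(matrix)
    return f.transform(matrix), f.report_


def minmax_normalize(matrix):
    """Min-max normalize every column into [0, 1]."""
    return RangeNormalizer().fit(matrix).transform(matrix)


def ward_cluster(matrix) -> Dendrogram:
    """Full Ward agglomeration of a normalized feature matrix."""
    return WardClusterer().fit(matrix).tree_


def assign_labels(tree: Dendrogram, k: int) -> np.ndarray:
    """Cut the dendrogram into k clusters (labels 1..k by decreasing size)."""
    return tree.cut(k)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr)
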