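"""Delaunay-threshold clustering of cDC1 point patterns.

Tissue cDC1s are scored as planar points (µm) with an optional binary marker
(Ki67).  A cluster is a connected component of the Delaunay triangulation
after removing every edge of length >= a distance threshold (40 µm by
default) — the "Delaunay cluster features" semantics of QuPath, which is not
the same as all-pairs distance thresholding.  Cluster-size statistics and
marker positivity by cluster size quantify local proliferation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import InvalidInputError

__all__ = [
    "PointPattern",
    "ClusterAssignment",
    "DelaunayThresholdClustering",
    "delaunay_threshold_clusters",
    "proximity_fraction",
    "marker_fraction_by_cluster_size",
    "DEFAULT_SIZE_BINS",
]

#: Cluster-size bins used in the Ki67 analysis: solitary/pairs, intermediate,
#: and clusters of at least five cells.
DEFAULT_SIZE_BINS = ((1, 2), (3, 4), (5, math.inf))


@dataclass
class PointPattern:
    """Marked planar point pattern in µm within a rectangular field."""

    coordinates: np.ndarray  # (n, 2)
    marker: np.ndarray | None = None  # binary flag per point
    field_size: tuple | None = None  # (width, height) in µm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise InvalidInputError("coordinates must be an (n, 2) array")
        if self.coordinates.shape[0] == 0:
            raise InvalidInputError("empty point pattern")
        if self.marker is not None:
            self.marker = np.asarray(self.marker).astype(int).ravel()
            if self.marker.size != self.coordinates.shape[0]:
                raise InvalidInputError("marker length must match point count")
            if not np.isin(self.marker, (0, 1)).all():
                raise InvalidInputError("marker must be binary")
        if self.field_size is not None:
            w, h = self.field_size
            x, y = self.coordinates[:, 0], self.coordinates[:, 1]
            if np.any(x < 0) or np.any(x > w) or np.any(y < 0) or np.any(y > h):
                raise InvalidInputError("points outside the field bounds")

    def __len__(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels per point plus the multiset of cluster sizes.

    Duplicated coordinates are merged before triangulation, so each size
    counts distinct positions; ``labels`` still has one entry per input
    point.
    """

    labels: np.ndarray  # cluster id per input point
    sizes: np.ndarray  # size per cluster id (distinct positions)
    threshold: float

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    def size_of(self, point_index) -> np.ndarray:
        """Cluster size for each queried point index."""
        return self.sizes[self.labels[point_index]]


def _triangulation_edges(points: np.ndarray) -> set:
    """Delaunay edge set; the complete graph for n < 3 or degenerate input."""
    n = points.shape[0]
    if n < 3:
        return set(combinations(range(n), 2))
    try:
        tri = Delaunay(points)
    except QhullError:
        # all points (near-)collinear: any valid "triangulation" degenerates;
        # fall back to the complete graph so thresholding still applies
        return set(combinations(range(n), 2))
    edges = set()
    for simplex in tri.simplices:
        for i, j in combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    return edges


class DelaunayThresholdClustering(ClusterMixin, BaseEstimator):
    """Connected components of the distance-thresholded Delaunay graph.

    Parameters
    ----------
    threshold : float
        Edges of Euclidean length >= ``threshold`` (µm) are removed before
        the connected-component search.  Default 40 µm.

    Fitted attributes
    -----------------
    labels_ : cluster id per input point
    cluster_sizes_ : number of distinct positions per cluster
    n_clusters_ : int
    """

    def __init__(self, threshold: float = 40.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidInputError("X must be an (n, 2) coordinate array")
        if X.shape[0] == 0:
            raise InvalidInputError("empty point pattern")
        if not self.threshold > 0:
            raise InvalidInputError("threshold must be positive")

        unique, inverse = np.unique(X, axis=0, return_inverse=True)
        if unique.shape[0] < X.shape[0]:
            warnings.warn(
                f"merged {X.shape[0] - unique.shape[0]} exactly coincident "
                "point(s) before triangulation",
                stacklevel=2,
            )
        edges = _triangulation_edges(unique)
        kept = [
            (i, j)
            for i, j in edges
            if np.hypot(*(unique[i] - unique[j])) < self.threshold
        ]
        m = unique.shape[0]
        if kept:
            ii, jj = np.array(kept).T
            adj = coo_matrix(
                (np.ones(ii.size), (ii, jj)), shape=(m, m)
            )
        else:
            adj = coo_matrix((m, m))
        n_comp, comp = connected_components(adj, directed=False)
        self.labels_ = comp[inverse]
        self.cluster_sizes_ = np.bincount(comp, minlength=n_comp)
        self.n_clusters_ = int(n_comp)
        self.n_features_in_ = 2
        return self

    def result(self) -> ClusterAssignment:
        return ClusterAssignment(
            labels=self.labels_,
            sizes=self.cluster_sizes_,
            threshold=self.threshold,
        )


def delaunay_threshold_clusters(
    pattern: PointPattern, threshold: float = 40.0
) -> ClusterAssignment:
    """Cluster a point pattern with the thresholded-Delaunay rule."""
    est = DelaunayThresholdClustering(threshold=threshold)
    est.fit(pattern.coordinates)
    return est.result()


def proximity_fraction(assignment: ClusterAssignment) -> float:
    """Percent of cells in clusters of size >= 2, i.e. within the Delaunay
    threshold of at least one other cell."""
    total = int(assignment.sizes.sum())
    in_clusters = int(assignment.sizes[assignment.sizes >= 2].sum())
    return 100.0 * in_clusters / total


def marker_fraction_by_cluster_size(
    pattern: PointPattern,
    assignment: ClusterAssignment,
    bins: Sequence[tuple] = DEFAULT_SIZE_BINS,
) -> dict:
    """Percent marker-positive cells per cluster-size bin.

    ``bins`` are inclusive ``(lo, hi)`` size ranges that must be disjoint and
    cover every observed cluster size.  Empty bins are reported as ``None``
    (undefined), not zero.
    """
    if pattern.marker is None:
        raise InvalidInputError("point pattern carries no marker flags")
    if len(pattern) != assignment.labels.size:
        raise InvalidInputError("pattern and assignment sizes disagree")
    for (a, b), (c, d) in combinations(bins, 2):
        if max(a, c) <= min(b, d):
            raise InvalidInputError("size bins must be disjoint")
    sizes = assignment.size_of(np.arange(len(pattern)))
    covered = np.zeros(len(pattern), dtype=bool)
    out = {}
    for lo, hi in bins:
        label = f"{int(lo)}-{int(hi)}" if math.isfinite(hi) else f">={int(lo)}"
        mask = (sizes >= lo) & (sizes <= hi)
        covered |= mask
        if mask.sum() == 0:
            out[label] = None
        else:
            out[label] = 100.0 * float(pattern.marker[mask].mean())
    if not covered.all():
        raise InvalidInputError(
            f"size bins do not cover cluster size(s) {sorted(set(sizes[~covered]))}"
        )
    return out
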