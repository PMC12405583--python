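"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import numpy as np
import pytest

from dcturnover import ModelParameters, gen_linear_photoconversion


# ---------------------------------------------------------------------------
# brute-force Delaunay oracle (independent of scipy.spatial.Delaunay)
# ---------------------------------------------------------------------------


def _orient(a, b, c):
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _in_circumcircle(a, b, c, d):
    """True if d lies strictly inside the circumcircle of triangle abc."""
    if _orient(a, b, c) < 0:
        b, c = c, b
    m = np.array(
        [
            [a[0] - d[0], a[1] - d[1], (a[0] - d[0]) ** 2 + (a[1] - d[1]) ** 2],
            [b[0] - d[0], b[1] - d[1], (b[0] - d[0]) ** 2 + (b[1] - d[1]) ** 2],
            [c[0] - d[0], c[1] - d[1], (c[0] - d[0]) ** 2 + (c[1] - d[1]) ** 2],
        ]
    )
    return np.linalg.det(m) > 0


def brute_force_delaunay_edges(points):
    """Edges of the Delaunay triangulation by exhaustive empty-circumcircle
    search over all triples (valid for small point sets in general position).
    Degenerate (all-collinear) inputs fall back to the complete graph, the
    same convention the implementation uses."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        return set(combinations(range(n), 2))
    edges = set()
    for i, j, k in combinations(range(n), 3):
        if abs(_orient(points[i], points[j], points[k])) < 1e-12:
            continue  # degenerate triple cannot be a triangle
        if any(
            _in_circumcircle(points[i], points[j], points[k], points[m])
            for m in range(n)
            if m not in (i, j, k)
        ):
            continue
        edges.update({(i, j), (i, k), (j, k)})
    if not edges:  # every triple collinear
        return set(combinations(range(n), 2))
    return edges


def brute_force_components(points, threshold):
    """Partition of points into thresholded-Delaunay components via
    union-find over the brute-force edge set."""
    points = np.asarray(points, dtype=float)
    parent = list(range(len(points)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in brute_force_delaunay_edges(points):
        if np.hypot(*(points[i] - points[j])) < threshold:
            parent[find(i)] = find(j)
    roots = [find(i) for i in range(len(points))]
    return canonical_partition(roots)


def canonical_partition(labels):
    """Relabel a partition by first appearance so partitions compare equal."""
    seen = {}
    out = []
    for x in labels:
        if x not in seen:
            seen[x] = len(seen)
        out.append(seen[x])
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def linear_tc():
    """Noise-free default SI photoconversion series (98.7 - 16.8 t)."""
    return gen_linear_photoconversion(noise=None, seed=0)


@pytest.fixture
def m2_params():
    return ModelParameters("M2", prolif_slope=0.1, max_residence=6.0,
                           efficiency=0.99)


@pytest.fixture
def m3_params():
    return ModelParameters("M3", prolif_slope=0.1, max_residence=6.0,
                           efflux_rate=0.05, efficiency=0.99)


@pytest.fixture
def two_triads():
    """Two well-separated triads: intra-spacing 15 µm, inter-spacing 200 µm,
    jittered to avoid cocircular degeneracy."""
    rng = np.random.default_rng(7)
    tri = np.array([[0.0, 0.0], [15.0, 0.0], [7.5, 13.0]])
    pts = np.vstack([tri, tri + np.array([200.0, 0.0])])
    return pts + rng.uniform(-1e-6, 1e-6, pts.shape)
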