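import numpy as np
import pytest

from cabbage3d import PointCloud


@pytest.fixture
def unit_cube():
    """The 8 corners of the unit cube [0,1]^3."""
    corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                       dtype=float)
    return PointCloud(corners)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    def make(n=100, scale=(1.0, 1.0, 1.0), colors=False, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        coords = r.normal(size=(n, 3)) * np.asarray(scale)
        cols = r.random((n, 3)) if colors else None
        return PointCloud(coords, cols)
    return make


def brute_force_mec(points):
    """Minimum enclosing circle by exhaustive pair/triple search (oracle)."""
    import itertools
    pts = np.asarray(points, dtype=float)
    best = None
    for i, j in itertools.combinations(range(len(pts)), 2):
        c = (pts[i] + pts[j]) / 2
        r = np.linalg.norm(pts[i] - c)
        if np.all(np.linalg.norm(pts - c, axis=1) <= r * (1 + 1e-10) + 1e-12):
            if best is None or r < best[1]:
                best = (c, r)
    for i, j, k in itertools.combinations(range(len(pts)), 3):
        a, b, c3 = pts[i], pts[j], pts[k]
        d = 2 * (a[0] * (b[1] - c3[1]) + b[0] * (c3[1] - a[1]) + c3[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        a2, b2, c2 = (a ** 2).sum(), (b ** 2).sum(), (c3 ** 2).sum()
        ux = (a2 * (b[1] - c3[1]) + b2 * (c3[1] - a[1]) + c2 * (a[1] - b[1])) / d
        uy = (a2 * (c3[0] - b[0]) + b2 * (a[0] - c3[0]) + c2 * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        r = np.linalg.norm(a - center)
        if np.all(np.linalg.norm(pts - center, axis=1) <= r * (1 + 1e-10) + 1e-12):
            if best is None or r < best[1]:
                best = (center, r)
    return best


def brute_force_hull_volume(points):
    """Hull volume from signed tetrahedra over an independent Delaunay route."""
    from scipy.spatial import Delaunay
    tri = Delaunay(points)
    vol = 0.0
    for simplex in tri.simplices:
        a, b, c, d = points[simplex]
        vol += abs(np.dot(a - d, np.cross(b - d, c - d))) / 6.0
    return vol
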