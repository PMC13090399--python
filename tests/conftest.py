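import numpy as np
import pytest

from surfmorph.mesh_io import LandmarkSet, TriMesh
from surfmorph.synthetic import ShapeParams, make_template

TETRA_VERTS = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)
TETRA_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


@pytest.fixture
def tetra():
    return TriMesh("tetra", TETRA_VERTS.copy(), TETRA_FACES.copy())


@pytest.fixture
def patch():
    """Small synthetic cranial patch with its landmarks."""
    return make_template(ShapeParams(), 200, specimen_id="patch")


@pytest.fixture
def patch_mesh(patch):
    return patch[0]


@pytest.fixture
def generic_landmarks():
    """Six generic non-coplanar landmarks in canonical naming."""
    rng = np.random.default_rng(7)
    pts = rng.normal(0.0, 20.0, (6, 3))
    names = (
        "bregma",
        "ophryon",
        "frontotemporale_L",
        "frontotemporale_R",
        "stephanion_L",
        "stephanion_R",
    )
    return LandmarkSet("generic", dict(zip(names, pts)))


def exhaustive_min_inertia(points, k):
    """Oracle: minimum within-cluster sum of squares over all k-partitions."""
    import itertools

    n = len(points)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        labels = np.asarray(labels)
        inertia = 0.0
        for c in range(k):
            members = points[labels == c]
            inertia += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return best


def brute_force_closest(query, mesh):
    """Independent oracle: exact closest point by looping over all faces."""
    best_d = np.inf
    best_p = None
    best_f = -1
    for fi, (ia, ib, ic) in enumerate(mesh.faces):
        p = _closest_on_triangle(
            np.asarray(query, float),
            mesh.vertices[ia],
            mesh.vertices[ib],
            mesh.vertices[ic],
        )
        d = np.linalg.norm(p - query)
        if d < best_d:
            best_d, best_p, best_f = d, p, fi
    return best_p, best_d, best_f


def _closest_on_triangle(p, a, b, c):
    """Scalar point-triangle closest point (Ericson), independent of the
    package's vectorized implementation."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return a + ab * v + ac * w
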