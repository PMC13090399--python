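import numpy as np
import pytest

from surfmorph.mesh_io import LandmarkSet, TriMesh, mean_edge_length
from surfmorph.registration import (
    ICPParams,
    RegisteredSample,
    SurfaceLocator,
    closest_point_on_mesh,
    default_icp_params,
    elastic_icp,
    register_sample,
    tps_apply,
    tps_fit,
)
from surfmorph.synthetic import ShapeParams, grid_uv, make_template, surface_point

from conftest import brute_force_closest


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------


def _probe_points(seed=0, n=20):
    return np.random.default_rng(seed).normal(0, 15, (n, 3))


def test_tps_identity(generic_landmarks):
    warp = tps_fit(generic_landmarks, generic_landmarks)
    probes = _probe_points()
    np.testing.assert_allclose(tps_apply(warp, probes), probes, atol=1e-9)


def test_tps_translation_affine_exactness(generic_landmarks):
    shifted = LandmarkSet(
        "t", {k: v + np.array([1.0, 0, 0]) for k, v in generic_landmarks.points.items()}
    )
    warp = tps_fit(generic_landmarks, shifted)
    probes = _probe_points(1)
    np.testing.assert_allclose(tps_apply(warp, probes), probes + [1.0, 0, 0], atol=1e-9)
    # nonaffine part vanishes for an affine correspondence
    assert np.abs(warp.nonaffine_weights).max() < 1e-9


def test_tps_general_affine_exactness(generic_landmarks):
    rng = np.random.default_rng(3)
    A = rng.normal(0, 1, (3, 3)) + 2 * np.eye(3)
    t = rng.normal(0, 5, 3)
    target = LandmarkSet(
        "t", {k: A @ v + t for k, v in generic_landmarks.points.items()}
    )
    warp = tps_fit(generic_landmarks, target)
    probes = _probe_points(2)
    np.testing.assert_allclose(tps_apply(warp, probes), probes @ A.T + t, atol=1e-8)


def test_tps_interpolates_controls_vs_dense_oracle(generic_landmarks):
    # oracle: solve the same interpolation conditions with lstsq on the full
    # (k+4) system assembled independently
    rng = np.random.default_rng(4)
    src = np.stack(list(generic_landmarks.points.values()))
    tgt = src + rng.normal(0, 2.0, src.shape)
    warp = tps_fit(src, tgt)
    np.testing.assert_allclose(tps_apply(warp, src), tgt, atol=1e-8)

    k = len(src)
    K = np.linalg.norm(src[:, None] - src[None], axis=-1)
    P = np.column_stack([np.ones(k), src])
    A = np.zeros((k + 4, k + 4))
    A[:k, :k] = K
    A[:k, k:] = P
    A[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = tgt
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    probes = _probe_points(5)
    U = np.linalg.norm(probes[:, None] - src[None], axis=-1)
    oracle = U @ sol[:k] + np.column_stack([np.ones(len(probes)), probes]) @ sol[k:]
    np.testing.assert_allclose(tps_apply(warp, probes), oracle, atol=1e-8)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_tps_interpolation_property(seed):
    # interpolating spline: controls always map exactly onto targets
    rng = np.random.default_rng(seed)
    src = rng.normal(0, 20, (6, 3))
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-6) < 3:
        return
    tgt = src + rng.normal(0, 3, (6, 3))
    warp = tps_fit(src, tgt)
    np.testing.assert_allclose(tps_apply(warp, src), tgt, atol=1e-8)


def test_tps_coplanar_rejected():
    src = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0], [1, 2, 0]], float
    )
    with pytest.raises(np.linalg.LinAlgError):
        tps_fit(src, src + 1.0)


def test_tps_too_few_controls():
    src = np.zeros((3, 3))
    with pytest.raises(ValueError):
        tps_fit(src, src)


# ---------------------------------------------------------------------------
# closest point
# ---------------------------------------------------------------------------


def test_closest_point_at_vertex(patch_mesh):
    q = patch_mesh.vertices[17]
    _, d, _ = closest_point_on_mesh(q, patch_mesh)
    assert d < 1e-12


def test_closest_point_above_face_centroid(tetra):
    a, b, c = tetra.vertices[tetra.faces[3]]
    centroid = (a + b + c) / 3
    n = np.cross(b - a, c - a)
    n /= np.linalg.norm(n)
    h = 0.3
    foot, d, face = closest_point_on_mesh(centroid + h * n, tetra)
    np.testing.assert_allclose(d, h, atol=1e-12)
    np.testing.assert_allclose(foot, centroid, atol=1e-12)
    assert face == 3


def test_closest_point_matches_brute_force(patch_mesh):
    rng = np.random.default_rng(6)
    lo = patch_mesh.vertices.min(axis=0) - 10
    hi = patch_mesh.vertices.max(axis=0) + 10
    queries = rng.uniform(lo, hi, (100, 3))
    locator = SurfaceLocator(patch_mesh)
    feet, dists, _ = locator.query(queries)
    for q, foot, d in zip(queries, feet, dists):
        _, d_bf, _ = brute_force_closest(q, patch_mesh)
        np.testing.assert_allclose(d, d_bf, atol=1e-9)


# ---------------------------------------------------------------------------
# elastic ICP
# ---------------------------------------------------------------------------


def _params(mesh, n=25, **kwargs):
    return default_icp_params(mesh, n_iterations=n, **kwargs)


def test_icp_identity_target(patch_mesh):
    out, trace = elastic_icp(patch_mesh, patch_mesh, _params(patch_mesh))
    np.testing.assert_allclose(out.vertices, patch_mesh.vertices, atol=1e-9)
    assert np.all(trace < 1e-9)


def test_icp_recovers_small_translation(patch_mesh):
    e = mean_edge_length(patch_mesh)
    params = _params(patch_mesh, n=60)
    shift = 0.5 * params.sigma_schedule[-1]
    target = patch_mesh.with_vertices(patch_mesh.vertices + [shift, 0.0, 0.0])
    out, _ = elastic_icp(patch_mesh, target, params)
    _, d, _ = SurfaceLocator(target).query(out.vertices)
    assert d.mean() < 0.01 * shift


def test_icp_preserves_topology(patch_mesh):
    tgt, _ = make_template(ShapeParams(brow_prominence=4.0), 200, specimen_id="t")
    out, trace = elastic_icp(patch_mesh, tgt, _params(patch_mesh))
    assert out.n_vertices == patch_mesh.n_vertices
    np.testing.assert_array_equal(out.faces, patch_mesh.faces)
    assert len(trace) == 25


def test_icp_improvement_property(patch_mesh):
    # final surface distance never worse than initial, on several target shapes
    for i, p in enumerate(
        [
            ShapeParams(brow_prominence=4.0),
            ShapeParams(squama_inclination=0.5),
            ShapeParams(squama_breadth=1.15),
        ]
    ):
        tgt, _ = make_template(p, 200, specimen_id=f"t{i}")
        loc = SurfaceLocator(tgt)
        initial = loc.query(patch_mesh.vertices)[1].mean()
        out, _ = elastic_icp(patch_mesh, tgt, _params(patch_mesh, n=40))
        final = loc.query(out.vertices)[1].mean()
        assert final <= initial


def test_icp_parametric_correspondence_oracle():
    # known ground-truth correspondence via the shared (u, v) grid
    ref, ref_lms = make_template(ShapeParams(brow_prominence=0.0), 2000, specimen_id="ref")
    p_t = ShapeParams(brow_prominence=3.0)
    tgt, tgt_lms = make_template(p_t, 2000, specimen_id="tgt")
    warp = tps_fit(ref_lms, tgt_lms)
    pre = ref.with_vertices(tps_apply(warp, ref.vertices))
    out, _ = elastic_icp(pre, tgt, _params(ref, n=40))
    edge = mean_edge_length(tgt)
    d_surf = SurfaceLocator(tgt).query(out.vertices)[1].mean()
    assert d_surf < edge
    u, v = grid_uv(2000)
    truth = surface_point(p_t, u, v)
    corr_err = np.linalg.norm(out.vertices - truth, axis=1).mean()
    assert corr_err < 3 * edge


def test_icp_accuracy_improves_with_resolution():
    errs = []
    for res in (300, 1200):
        ref, ref_lms = make_template(ShapeParams(), res, specimen_id="ref")
        p_t = ShapeParams(brow_prominence=4.0, squama_inclination=0.45)
        tgt, tgt_lms = make_template(p_t, res, specimen_id="tgt")
        pre = ref.with_vertices(tps_apply(tps_fit(ref_lms, tgt_lms), ref.vertices))
        out, _ = elastic_icp(pre, tgt, _params(ref, n=40))
        u, v = grid_uv(res)
        truth = surface_point(p_t, u, v)
        errs.append(np.linalg.norm(out.vertices - truth, axis=1).mean())
    assert errs[1] < errs[0]


def test_icp_deterministic_with_full_fraction(patch_mesh):
    tgt, _ = make_template(ShapeParams(brow_prominence=3.0), 200, specimen_id="t")
    p = _params(patch_mesh)
    a, _ = elastic_icp(patch_mesh, tgt, p)
    b, _ = elastic_icp(patch_mesh, tgt, p)
    np.testing.assert_array_equal(a.vertices, b.vertices)


def test_icp_stochastic_fraction_seeded(patch_mesh):
    tgt, _ = make_template(ShapeParams(brow_prominence=3.0), 200, specimen_id="t")
    p1 = _params(patch_mesh, stochastic_fraction=0.5, seed=1)
    p2 = _params(patch_mesh, stochastic_fraction=0.5, seed=2)
    a, _ = elastic_icp(patch_mesh, tgt, p1)
    a2, _ = elastic_icp(patch_mesh, tgt, p1)
    b, _ = elastic_icp(patch_mesh, tgt, p2)
    np.testing.assert_array_equal(a.vertices, a2.vertices)
    assert np.abs(a.vertices - b.vertices).max() > 0


def test_icp_params_validation(patch_mesh):
    with pytest.raises(ValueError):
        ICPParams(sigma_schedule=[])
    with pytest.raises(ValueError):
        ICPParams(sigma_schedule=[1.0, 2.0])  # increasing
    with pytest.raises(ValueError):
        ICPParams(sigma_schedule=[1.0], step_fraction=0.0)
    with pytest.raises(ValueError):
        ICPParams(sigma_schedule=[1.0], correspondence_mode="magic")


# ---------------------------------------------------------------------------
# register_sample
# ---------------------------------------------------------------------------


def test_register_reference_as_target(patch):
    ref, lms = patch
    sample = register_sample(ref, lms, [(ref.copy(), lms.copy())], _params(ref))
    assert sample.n_specimens == 2
    np.testing.assert_allclose(
        sample.coordinates[0], sample.coordinates[1], atol=1e-6
    )


def test_register_with_subsample_shape_contract(patch):
    ref, lms = patch
    targets = []
    for i, brow in enumerate((1.0, 2.0, 3.0, 4.0, 5.0)):
        m, l = make_template(ShapeParams(brow_prominence=brow), 200, specimen_id=f"t{i}")
        targets.append((m, l))
    sample = register_sample(ref, lms, targets, _params(ref, n=10), k=100)
    assert sample.coordinates.shape == (6, 100, 3)
    assert len(sample.subsample_indices) == 100
    assert sample.faces is None


def test_register_deterministic(patch):
    ref, lms = patch
    tgt = make_template(ShapeParams(brow_prominence=3.0), 200, specimen_id="t")
    p = _params(ref, n=10)
    a = register_sample(ref, lms, [tgt], p)
    b = register_sample(ref, lms, [tgt], p)
    np.testing.assert_array_equal(a.coordinates, b.coordinates)
    assert a.seeds == b.seeds


def test_register_invalid_target_named(patch):
    ref, lms = patch
    bad = TriMesh(
        "broken",
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5], [6, 5, 5], [5, 6, 5.0]]),
        np.array([[0, 1, 2], [3, 4, 5]]),
    )
    from surfmorph.synthetic import template_landmarks

    with pytest.raises(ValueError, match="broken"):
        register_sample(ref, lms, [(bad, template_landmarks(ShapeParams(), "broken"))], _params(ref))


def test_registered_sample_round_trip(tmp_path, patch):
    ref, lms = patch
    tgt = make_template(ShapeParams(brow_prominence=3.0), 200, specimen_id="t")
    sample = register_sample(ref, lms, [tgt], _params(ref, n=5))
    sample.save_dir(tmp_path / "sample")
    back = RegisteredSample.load_dir(tmp_path / "sample")
    np.testing.assert_allclose(back.coordinates, sample.coordinates, atol=1e-12)
    assert back.specimen_ids == sample.specimen_ids
    assert back.seeds == sample.seeds
    np.testing.assert_array_equal(back.faces, sample.faces)
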