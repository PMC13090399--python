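import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surfmorph.mesh_io import TriMesh
from surfmorph.shape_stats import (
    allometry_test,
    centroid_size,
    gpa,
    mahalanobis_to_groups,
    pairwise_opa_distance,
    pca_shape,
    pd_report,
    procrustes_distance,
    project_specimen,
    surface_area,
    warp_along_pc,
)


def _random_configs(s=6, n=20, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 10, (n, 3))
    return np.stack([base + rng.normal(0, 0.5, (n, 3)) for _ in range(s)])


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


def test_gpa_aligns_similarity_copies():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 5, (15, 3))
    copy = 2.5 * base @ _random_rotation(rng) + rng.normal(0, 20, 3)
    space = gpa(np.stack([base, copy]))
    np.testing.assert_allclose(
        space.procrustes_coords[0], space.procrustes_coords[1], atol=1e-8
    )


def test_gpa_unit_centroid_size_and_origin():
    space = gpa(_random_configs())
    for cfg in space.procrustes_coords:
        np.testing.assert_allclose(centroid_size(cfg), 1.0, atol=1e-9)
        np.testing.assert_allclose(cfg.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(centroid_size(space.mean_shape), 1.0, atol=1e-9)


def test_gpa_two_specimen_matches_closed_form():
    # oracle: one-shot full Procrustes of two configurations (centered, unit
    # scaled, optimal rotation by SVD), computed independently
    rng = np.random.default_rng(2)
    a = rng.normal(0, 4, (10, 3))
    b = a + rng.normal(0, 1.0, (10, 3))
    space = gpa(np.stack([a, b]))
    d_gpa = procrustes_distance(space.procrustes_coords[0], space.procrustes_coords[1])

    A = a - a.mean(axis=0)
    B = b - b.mean(axis=0)
    A /= np.linalg.norm(A)
    B /= np.linalg.norm(B)
    U, s, Vt = np.linalg.svd(A.T @ B)
    if np.linalg.det(U @ Vt) < 0:
        s = s.copy()
        s[-1] *= -1
    # closed form: |A R - B|^2 = 2 - 2 * sum singular values (with det fix)
    d_oracle = np.sqrt(max(0.0, 2.0 - 2.0 * s.sum()))
    np.testing.assert_allclose(d_gpa, d_oracle, atol=1e-8)
    np.testing.assert_allclose(pairwise_opa_distance(a, b), d_oracle, atol=1e-8)


def test_gpa_invariant_to_input_similarity():
    configs = _random_configs(s=5, seed=3)
    space0 = gpa(configs)
    rng = np.random.default_rng(4)
    configs2 = configs.copy()
    configs2[2] = 3.0 * configs[2] @ _random_rotation(rng) + rng.normal(0, 50, 3)
    space1 = gpa(configs2)
    np.testing.assert_allclose(
        space0.procrustes_coords, space1.procrustes_coords, atol=1e-8
    )


def test_gpa_degenerate_configuration_named():
    configs = _random_configs(s=3)
    configs[1] = 0.0
    with pytest.raises(ValueError, match="s1"):
        gpa(configs)


def test_gpa_rejects_tiny_input():
    with pytest.raises(ValueError):
        gpa(np.zeros((1, 5, 3)))


# ---------------------------------------------------------------------------
# PCA / projection / warps
# ---------------------------------------------------------------------------


def test_pca_variance_fractions_sum_to_one():
    space = pca_shape(gpa(_random_configs(s=8)))
    np.testing.assert_allclose(space.variance_fraction.sum(), 1.0, atol=1e-9)
    assert np.all(np.diff(space.variance_fraction) <= 1e-12)


def test_pca_single_direction_of_variation():
    # inject an exactly rank-1 family of superimposed coordinates
    rng = np.random.default_rng(5)
    space = gpa(_random_configs(s=5, n=12, seed=5))
    base = space.procrustes_coords[0]
    direction = rng.normal(0, 1, base.shape)
    space.procrustes_coords = np.stack(
        [base + t * 0.001 * direction for t in (-2, -1, 0, 1, 2)]
    )
    space = pca_shape(space)
    np.testing.assert_allclose(space.variance_fraction[0], 1.0, atol=1e-9)


def test_pca_reconstruction_identity():
    space = pca_shape(gpa(_random_configs(s=7, seed=6)))
    flat = space.procrustes_coords.reshape(space.n_specimens, -1)
    recon = space.fit_mean + space.pc_scores @ space.pc_vectors
    np.testing.assert_allclose(recon, flat, atol=1e-8)


def test_pca_scores_centered():
    space = pca_shape(gpa(_random_configs(s=7, seed=7)))
    np.testing.assert_allclose(space.pc_scores.mean(axis=0), 0.0, atol=1e-9)


def test_project_fit_specimen_reproduces_scores():
    space = pca_shape(gpa(_random_configs(s=6, seed=8)))
    for i in range(space.n_specimens):
        proj = project_specimen(space, space.procrustes_coords[i])
        np.testing.assert_allclose(proj, space.pc_scores[i], atol=1e-9)


def test_project_fit_mean_is_zero():
    space = pca_shape(gpa(_random_configs(s=6, seed=9)))
    proj = project_specimen(space, space.fit_mean.reshape(-1, 3))
    np.testing.assert_allclose(proj, 0.0, atol=1e-9)


def test_project_held_out_specimen_within_range():
    configs = _random_configs(s=20, seed=10)
    space = gpa(configs)
    held_out = space.specimen_ids[-1]
    space = pca_shape(space, fit_ids=space.specimen_ids[:-1])
    scores = space.pc_scores
    fit_rows = list(range(19))
    for c in range(min(3, scores.shape[1])):
        lo, hi = scores[fit_rows, c].min(), scores[fit_rows, c].max()
        margin = (hi - lo) * 0.5
        assert lo - margin <= scores[19, c] <= hi + margin


def test_warp_zero_multiplier_is_mean():
    space = pca_shape(gpa(_random_configs(s=6, seed=11)))
    np.testing.assert_allclose(
        warp_along_pc(space, 0, 0.0).reshape(-1), space.fit_mean, atol=1e-12
    )


def test_warp_symmetry():
    space = pca_shape(gpa(_random_configs(s=6, seed=12)))
    plus = warp_along_pc(space, 0, 2.0)
    minus = warp_along_pc(space, 0, -2.0)
    mean = space.fit_mean.reshape(-1, 3)
    np.testing.assert_allclose(plus - mean, -(minus - mean), atol=1e-9)


def test_warp_reproduces_truncated_reconstruction():
    space = pca_shape(gpa(_random_configs(s=6, seed=13)))
    i, pc = 2, 0
    sd = np.std(space.pc_scores[:, pc], ddof=1)
    warped = warp_along_pc(space, pc, space.pc_scores[i, pc] / sd)
    trunc = space.fit_mean + space.pc_scores[i, pc] * space.pc_vectors[pc]
    np.testing.assert_allclose(warped.reshape(-1), trunc, atol=1e-9)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_pd_basic_properties():
    rng = np.random.default_rng(14)
    a = rng.normal(0, 1, (8, 3))
    b = rng.normal(0, 1, (8, 3))
    assert procrustes_distance(a, a) == 0.0
    assert procrustes_distance(a, b) == procrustes_distance(b, a)
    with pytest.raises(ValueError):
        procrustes_distance(a, b[:5])


def test_pd_matches_hand_computation():
    a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    b = a + np.array([[0.1, 0, 0], [0, 0.2, 0], [0, 0, 0.2], [0.1, 0, 0]])
    # flatten-and-norm by hand: sqrt(0.01 + 0.04 + 0.04 + 0.01) = sqrt(0.10)
    np.testing.assert_allclose(procrustes_distance(a, b), np.sqrt(0.10), atol=1e-12)


def test_pd_report_stats_and_sorting():
    # three specimens in one group at PDs 0.1/0.2/0.3 from the focal
    base = np.zeros((4, 3))
    base[1] = [1.0, 0, 0]
    base[2] = [0, 1.0, 0]
    base[3] = [0, 0, 1.0]
    configs = [base]
    for d in (0.3, 0.1, 0.2):  # deliberately unsorted
        c = base.copy()
        c[0, 0] += d
        configs.append(c)
    space = gpa(np.stack([base] * 4))  # placeholder superimposition
    space.procrustes_coords = np.stack(configs)  # inject exact coordinates
    study = pd.DataFrame(
        {"specimen_id": ["s0", "s1", "s2", "s3"], "group": ["f", "g", "g", "g"]}
    )
    report = pd_report(space, "s0", study)
    assert "s0" not in set(report.table["specimen_id"])
    g = report.table[report.table["group"] == "g"]
    np.testing.assert_allclose(g["pd"].to_numpy(), [0.1, 0.2, 0.3], atol=1e-12)
    row = report.group_stats[report.group_stats["group"] == "g"].iloc[0]
    np.testing.assert_allclose(row["mean"], 0.2, atol=1e-12)
    np.testing.assert_allclose(row["sd"], 0.1, atol=1e-12)  # sample SD


def test_mahalanobis_at_group_mean_is_zero():
    space = pca_shape(gpa(_random_configs(s=8, seed=15)))
    study = pd.DataFrame(
        {
            "specimen_id": space.specimen_ids,
            "group": ["g"] * 8,
        }
    )
    # put the focal exactly at the group mean in score space
    others = [s for s in space.specimen_ids if s != "s0"]
    rows = [space.index_of(s) for s in others]
    space.pc_scores[0, :2] = space.pc_scores[rows, :2].mean(axis=0)
    md = mahalanobis_to_groups(space, "s0", study[study.specimen_id != "s0"], m=2)
    np.testing.assert_allclose(md["g"], 0.0, atol=1e-9)


def test_mahalanobis_identity_covariance_is_euclidean():
    space = pca_shape(gpa(_random_configs(s=10, seed=16)))
    # force scores whose group covariance is the identity (zero shrinkage
    # effect: shrinkage of identity toward its diagonal is identity)
    controlled = np.array(
        [
            [1.0, 1.0],
            [1, -1],
            [-1, 1],
            [-1, -1],
            [2, 0],
            [-2, 0],
            [0, 2],
            [0, -2],
            [0, 0],
        ]
    ) * np.sqrt(8 / 12)  # per-column SS is 12; rescale so ddof=1 cov = I
    scores = np.vstack([[3.0, 4.0], controlled])
    cov = np.cov(scores[1:], rowvar=False, ddof=1)
    np.testing.assert_allclose(cov, np.eye(2), atol=1e-12)
    space.pc_scores = np.hstack([scores, np.zeros((10, space.pc_scores.shape[1] - 2))])
    study = pd.DataFrame({"specimen_id": space.specimen_ids, "group": ["g"] * 10})
    md = mahalanobis_to_groups(space, "s0", study[study.specimen_id != "s0"], m=2, shrinkage=0.3)
    np.testing.assert_allclose(md["g"], 5.0, atol=1e-9)  # 3-4-5 triangle


def test_mahalanobis_hand_computed_2d():
    space = pca_shape(gpa(_random_configs(s=5, seed=17)))
    scores = np.array([[2.0, 0.0], [1, 1], [-1, 1], [1, -1], [-1, -1]])
    space.pc_scores = np.hstack([scores, np.zeros((5, space.pc_scores.shape[1] - 2))])
    study = pd.DataFrame({"specimen_id": space.specimen_ids, "group": ["g"] * 5})
    lam = 0.1
    G = scores[1:]
    S = np.cov(G, rowvar=False, ddof=1)
    S_sh = (1 - lam) * S + lam * np.diag(np.diag(S))
    diff = scores[0] - G.mean(axis=0)
    expected = np.sqrt(diff @ np.linalg.inv(S_sh) @ diff)
    md = mahalanobis_to_groups(space, "s0", study[study.specimen_id != "s0"], m=2, shrinkage=lam)
    np.testing.assert_allclose(md["g"], expected, atol=1e-12)


def test_mahalanobis_m_too_large_names_group():
    space = pca_shape(gpa(_random_configs(s=5, seed=18)))
    study = pd.DataFrame(
        {"specimen_id": space.specimen_ids, "group": ["g", "small", "small", "g", "g"]}
    )
    with pytest.raises(ValueError, match="small"):
        mahalanobis_to_groups(space, "s0", study[study.specimen_id != "s0"], m=3)


# ---------------------------------------------------------------------------
# surface area & allometry
# ---------------------------------------------------------------------------


def test_surface_area_single_triangle():
    mesh = TriMesh(
        "t", np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]), np.array([[0, 1, 2]])
    )
    np.testing.assert_allclose(surface_area(mesh), 0.5)  # 50 mm^2 = 0.5 cm^2


def test_surface_area_scales_quadratically(patch_mesh):
    scaled = patch_mesh.with_vertices(patch_mesh.vertices * 3.0)
    np.testing.assert_allclose(surface_area(scaled), 9.0 * surface_area(patch_mesh), rtol=1e-12)


def test_surface_area_vs_per_face_oracle(patch_mesh):
    total = 0.0
    for ia, ib, ic in patch_mesh.faces:  # independent per-face summation
        a, b, c = patch_mesh.vertices[[ia, ib, ic]]
        ab, ac = b - a, c - a
        cross = np.array(
            [
                ab[1] * ac[2] - ab[2] * ac[1],
                ab[2] * ac[0] - ab[0] * ac[2],
                ab[0] * ac[1] - ab[1] * ac[0],
            ]
        )
        total += 0.5 * np.sqrt((cross**2).sum())
    np.testing.assert_allclose(surface_area(patch_mesh), total / 100.0, atol=1e-9)


def test_allometry_df():
    rng = np.random.default_rng(19)
    areas = rng.uniform(50, 150, 45)
    scores = rng.normal(0, 1, 45)
    res = allometry_test(scores, areas)
    assert res.df == 43


def test_allometry_perfect_fit():
    areas = np.linspace(50, 150, 20)
    scores = 2.0 * np.log(areas)
    res = allometry_test(scores, areas)
    np.testing.assert_allclose(res.correlation_r, 1.0, atol=1e-12)
    np.testing.assert_allclose(res.slope, 2.0, atol=1e-9)
    np.testing.assert_allclose(res.residual_se, 0.0, atol=1e-9)
    assert res.p_value <= 0.05 and res.significant


def test_allometry_p_matches_t_identity():
    rng = np.random.default_rng(20)
    areas = rng.uniform(10, 100, 30)
    scores = rng.normal(0, 1, 30)
    res = allometry_test(scores, areas)
    t = res.correlation_r * np.sqrt(res.df / (1 - res.correlation_r**2))
    p = 2 * stats.t.sf(abs(t), res.df)
    np.testing.assert_allclose(res.t_value, t, atol=1e-12)
    np.testing.assert_allclose(res.p_value, p, atol=1e-12)


def test_allometry_zero_variance_rejected():
    with pytest.raises(ValueError):
        allometry_test(np.ones(10), np.linspace(10, 20, 10))
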