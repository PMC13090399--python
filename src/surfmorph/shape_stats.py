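"""Shape statistics on dense corresponding coordinates.

Generalized Procrustes superimposition, shape PCA with out-of-sample
projection and PC warps, Procrustes and Mahalanobis distances, surface area
and static allometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mesh_io import TriMesh
from .registration import RegisteredSample

__all__ = [
    "ShapeSpace",
    "AllometryResult",
    "DistanceReport",
    "gpa",
    "pca_shape",
    "project_specimen",
    "warp_along_pc",
    "procrustes_distance",
    "pd_report",
    "mahalanobis_to_groups",
    "surface_area",
    "allometry_test",
    "centroid_size",
]


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared distances from the configuration's
    centroid."""
    c = np.asarray(config, dtype=float)
    return float(np.linalg.norm(c - c.mean(axis=0)))


@dataclass
class ShapeSpace:
    """GPA superimposition plus (optionally) its PCA decomposition."""

    specimen_ids: list[str]
    procrustes_coords: np.ndarray  # (s, n, 3), unit centroid size each
    centroid_sizes: np.ndarray  # (s,), mm
    mean_shape: np.ndarray  # (n, 3), unit centroid size
    pc_scores: np.ndarray | None = None  # (s, c)
    pc_vectors: np.ndarray | None = None  # (c, 3n), orthonormal rows
    variance_fraction: np.ndarray | None = None  # (c,)
    fit_ids: list[str] | None = None
    fit_mean: np.ndarray | None = None  # (3n,) PCA centering vector

    @property
    def n_specimens(self) -> int:
        return self.procrustes_coords.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.procrustes_coords.shape[1]

    def index_of(self, specimen_id: str) -> int:
        try:
            return self.specimen_ids.index(specimen_id)
        except ValueError as exc:
            raise KeyError(f"unknown specimen '{specimen_id}'") from exc

    def configuration(self, specimen_id: str) -> np.ndarray:
        return self.procrustes_coords[self.index_of(specimen_id)]


@dataclass
class AllometryResult:
    """Pearson test of one PC against log surface area."""

    pc_index: int
    df: int
    t_value: float
    correlation_r: float
    slope: float
    residual_se: float
    p_value: float
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_value <= 0.05


@dataclass
class DistanceReport:
    """Pairwise Procrustes distances from one focal specimen, by group."""

    focal_id: str
    table: pd.DataFrame  # columns specimen_id, group, pd; sorted within group
    group_stats: pd.DataFrame  # columns group, mean, sd


def _optimal_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections disallowed) minimizing |X R - Y|."""
    U, _, Vt = np.linalg.svd(X.T @ Y)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def gpa(
    sample: RegisteredSample | np.ndarray,
    specimen_ids: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ShapeSpace:
    """Generalized Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size and rotated
    to the running mean; the mean is re-estimated (and re-scaled to unit
    size) until it moves less than ``tol``.
    """
    if isinstance(sample, RegisteredSample):
        coords = sample.coordinates
        ids = list(sample.specimen_ids)
    else:
        coords = np.asarray(sample, dtype=float)
        ids = specimen_ids if specimen_ids is not None else [f"s{i}" for i in range(len(coords))]
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("expected (specimens, vertices, 3) coordinates")
    s, n, _ = coords.shape
    if s < 2 or n < 3:
        raise ValueError("GPA needs >= 2 specimens and >= 3 vertices")

    X = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.linalg.norm(X, axis=(1, 2))
    for i, cs in enumerate(sizes):
        if cs < 1e-12:
            raise ValueError(f"degenerate configuration '{ids[i]}' (all points coincide)")
    X = X / sizes[:, None, None]

    mean = X[0].copy()
    mean /= np.linalg.norm(mean)
    for _ in range(max_iter):
        for i in range(s):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    # canonical global frame: GPA is otherwise defined only up to one common
    # rotation (it inherits the first specimen's arbitrary orientation)
    R = _canonical_frame(mean)
    mean = mean @ R
    for i in range(s):
        X[i] = (X[i] @ R) @ _optimal_rotation(X[i] @ R, mean)
    return ShapeSpace(
        specimen_ids=ids,
        procrustes_coords=X,
        centroid_sizes=sizes,
        mean_shape=mean,
    )


def _canonical_frame(config: np.ndarray) -> np.ndarray:
    """Proper rotation aligning the configuration's principal axes with the
    coordinate axes, signs fixed deterministically (largest-|coordinate|
    vertex positive on axes 1-2; axis 3 sign keeps det = +1)."""
    _, _, Vt = np.linalg.svd(config - config.mean(axis=0), full_matrices=False)
    R = Vt.T
    rotated = config @ R
    for j in range(2):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            R[:, j] *= -1.0
    if np.linalg.det(R) < 0:
        R[:, 2] *= -1.0
    return R


def pca_shape(space: ShapeSpace, fit_ids: list[str] | None = None) -> ShapeSpace:
    """PCA of the flattened Procrustes coordinates.

    The decomposition is fitted (centered) on ``fit_ids`` (default: all
    specimens); scores are stored for every specimen, non-fit ones by
    projection.  Component signs are fixed deterministically (largest-
    magnitude loading positive).
    """
    ids = space.specimen_ids
    fit = list(fit_ids) if fit_ids is not None else list(ids)
    if len(fit) < 2:
        raise ValueError("PCA needs at least 2 fit specimens")
    fit_rows = [space.index_of(i) for i in fit]
    flat = space.procrustes_coords.reshape(space.n_specimens, -1)
    mu = flat[fit_rows].mean(axis=0)
    Xc = flat[fit_rows] - mu
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(len(fit) - 1, Xc.shape[1])
    svals, Vt = svals[:ncomp], Vt[:ncomp]
    # deterministic sign: biggest-|loading| entry of each component positive
    for i in range(ncomp):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
    var = svals**2
    total = var.sum()
    space.pc_vectors = Vt
    space.variance_fraction = var / total if total > 0 else var
    space.pc_scores = (flat - mu) @ Vt.T
    space.fit_ids = fit
    space.fit_mean = mu
    return space


def project_specimen(space: ShapeSpace, configuration: np.ndarray) -> np.ndarray:
    """Project an already-superimposed configuration into the fitted PCA."""
    if space.pc_vectors is None or space.fit_mean is None:
        raise ValueError("PCA has not been fitted")
    flat = np.asarray(configuration, dtype=float).reshape(-1)
    if flat.shape[0] != space.fit_mean.shape[0]:
        raise ValueError("configuration dimension mismatch")
    return (flat - space.fit_mean) @ space.pc_vectors.T


def warp_along_pc(space: ShapeSpace, pc: int, multiplier: float) -> np.ndarray:
    """Mean shape displaced along one PC by ``multiplier`` score SDs."""
    if space.pc_vectors is None or space.pc_scores is None:
        raise ValueError("PCA has not been fitted")
    if not (0 <= pc < len(space.pc_vectors)):
        raise ValueError(f"pc index {pc} out of range")
    fit_rows = [space.index_of(i) for i in (space.fit_ids or space.specimen_ids)]
    sd = float(np.std(space.pc_scores[fit_rows, pc], ddof=1))
    flat = space.fit_mean + multiplier * sd * space.pc_vectors[pc]
    return flat.reshape(-1, 3)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the coordinate-wise difference of two configurations
    superimposed in the same GPA (not re-fitted pairwise)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations have different vertex counts")
    return float(np.linalg.norm(a - b))


def pairwise_opa_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Alternative: full Procrustes distance after a fresh pairwise
    superimposition (centering, unit scaling, optimal rotation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations have different vertex counts")
    A = a - a.mean(axis=0)
    B = b - b.mean(axis=0)
    A /= np.linalg.norm(A)
    B /= np.linalg.norm(B)
    return float(np.linalg.norm(A @ _optimal_rotation(A, B) - B))


def pd_report(
    space: ShapeSpace, focal: str, groups: pd.DataFrame
) -> DistanceReport:
    """Pairwise PDs from the focal specimen to every other, grouped and
    sorted ascending within group; per-group mean and sample SD."""
    focal_row = space.index_of(focal)
    gmap = dict(zip(groups["specimen_id"], groups["group"]))
    rows = []
    for i, sid in enumerate(space.specimen_ids):
        if sid == focal:
            continue
        d = procrustes_distance(
            space.procrustes_coords[focal_row], space.procrustes_coords[i]
        )
        rows.append({"specimen_id": sid, "group": gmap.get(sid, "?"), "pd": d})
    table = (
        pd.DataFrame(rows)
        .sort_values(["group", "pd"], kind="stable")
        .reset_index(drop=True)
    )
    stats_rows = []
    for g, sub in table.groupby("group", sort=False):
        stats_rows.append(
            {
                "group": g,
                "mean": float(sub["pd"].mean()),
                "sd": float(sub["pd"].std(ddof=1)) if len(sub) > 1 else float("nan"),
            }
        )
    return DistanceReport(focal, table, pd.DataFrame(stats_rows))


def mahalanobis_to_groups(
    space: ShapeSpace,
    focal: str,
    groups: pd.DataFrame,
    m: int = 2,
    shrinkage: float = 0.1,
) -> dict[str, float]:
    """Mahalanobis distance from the focal specimen to each group mean,
    computed in the leading-m PC-score subspace with covariance shrinkage
    toward the diagonal."""
    if space.pc_scores is None:
        raise ValueError("PCA has not been fitted")
    scores = space.pc_scores[:, :m]
    x = scores[space.index_of(focal)]
    gmap = dict(zip(groups["specimen_id"], groups["group"]))
    out: dict[str, float] = {}
    for g in pd.unique(groups["group"]):
        members = [
            i
            for i, sid in enumerate(space.specimen_ids)
            if sid != focal and gmap.get(sid) == g
        ]
        if len(members) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 members")
        if m > len(members) - 1:
            raise ValueError(
                f"subspace dimension m={m} too large for group '{g}' (n={len(members)})"
            )
        G = scores[members]
        mu = G.mean(axis=0)
        S = np.cov(G, rowvar=False, ddof=1).reshape(m, m)
        S = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
        diff = x - mu
        out[g] = float(np.sqrt(diff @ np.linalg.solve(S, diff)))
    return out


def surface_area(mesh: TriMesh) -> float:
    """Total triangle area in cm^2 (coordinates are mm; mm^2 / 100)."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum() / 100.0)


def allometry_test(
    scores: np.ndarray, areas_cm2: np.ndarray, pc_index: int = 0
) -> AllometryResult:
    """Static allometry: Pearson test and least-squares fit of a PC score on
    natural-log surface area."""
    y = np.asarray(scores, dtype=float)
    areas = np.asarray(areas_cm2, dtype=float)
    if len(y) != len(areas):
        raise ValueError("scores and areas length mismatch")
    n = len(y)
    if n < 3:
        raise ValueError("allometry test needs n >= 3")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    x = np.log(areas)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    df = n - 2
    resid = y - (res.intercept + res.slope * x)
    residual_se = float(np.sqrt(np.sum(resid**2) / df))
    if abs(r) >= 1.0:
        t = float("inf") if r > 0 else float("-inf")
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return AllometryResult(
        pc_index=pc_index,
        df=df,
        t_value=float(t),
        correlation_r=r,
        slope=float(res.slope),
        residual_se=residual_se,
        p_value=float(p),
    )
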