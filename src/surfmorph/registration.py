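"""Dense surface registration: TPS landmark warp followed by elastic ICP.

The reference mesh is first carried onto each target by an interpolating 3D
thin-plate spline fitted to the six registration landmarks, then deformed by
an elastic iterative-closest-point loop: per-vertex closest-point
displacements are smoothed with a Gaussian kernel over the reference
vertices, capped, and applied fractionally.  The deformed copy keeps the
reference's vertex/face structure, which is what establishes dense
correspondence across specimens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .mesh_io import LandmarkSet, TriMesh, mean_edge_length, validate_single_layer

__all__ = [
    "TPSWarp",
    "ICPParams",
    "RegisteredSample",
    "tps_fit",
    "tps_apply",
    "closest_point_on_mesh",
    "SurfaceLocator",
    "elastic_icp",
    "register_sample",
    "default_icp_params",
]


# ---------------------------------------------------------------------------
# Thin-plate spline (3D, kernel U(r) = r)
# ---------------------------------------------------------------------------


@dataclass
class TPSWarp:
    """Interpolating 3D thin-plate spline fitted to paired control points."""

    control_source: np.ndarray  # (k, 3)
    control_target: np.ndarray  # (k, 3)
    affine_part: np.ndarray  # (4, 3): row 0 = translation, rows 1-3 = linear
    nonaffine_weights: np.ndarray  # (k, 3)


def tps_fit(source: LandmarkSet | np.ndarray, target: LandmarkSet | np.ndarray) -> TPSWarp:
    """Fit the interpolating spline mapping source landmarks onto target.

    Uses the 3D biharmonic kernel U(r) = r.  Exact at the controls; reduces
    to its affine part when the target is an affine image of the source.
    """
    if isinstance(source, LandmarkSet) and isinstance(target, LandmarkSet):
        names = source.names
        if set(names) != set(target.names):
            raise ValueError("source and target landmark names differ")
        src = source.array(names)
        tgt = target.array(names)
    else:
        src = np.asarray(source, dtype=float).reshape(-1, 3)
        tgt = np.asarray(target, dtype=float).reshape(-1, 3)
        if src.shape != tgt.shape:
            raise ValueError("source and target control shapes differ")
    k = len(src)
    if k < 4:
        raise ValueError("TPS needs at least 4 control points")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(src).max())) < 3:
        raise np.linalg.LinAlgError("control points are coplanar; TPS system singular")

    K = cdist(src, src)  # U(r) = r
    P = np.column_stack([np.ones(k), src])
    A = np.zeros((k + 4, k + 4))
    A[:k, :k] = K
    A[:k, k:] = P
    A[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = tgt
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"degenerate TPS system: {exc}") from exc
    return TPSWarp(src, tgt, affine_part=sol[k:], nonaffine_weights=sol[:k])


def tps_apply(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Apply the warp to an (n, 3) array of points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    U = cdist(pts, warp.control_source)
    out = U @ warp.nonaffine_weights
    out += warp.affine_part[0]
    out += pts @ warp.affine_part[1:]
    return out


# ---------------------------------------------------------------------------
# Exact closest point on a triangulated surface
# ---------------------------------------------------------------------------


def _point_triangle_closest(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized closest point on triangle(s) abc to point(s) p.

    All inputs (n, 3); returns (n, 3).  Standard barycentric region test
    (Ericson, Real-Time Collision Detection).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge ab
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    if m.any():
        t = d1[m] / (d1[m] - d3[m])
        out[m] = a[m] + t[:, None] * ab[m]
        done |= m
    # edge ac
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    if m.any():
        t = d2[m] / (d2[m] - d6[m])
        out[m] = a[m] + t[:, None] * ac[m]
        done |= m
    # edge bc
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    if m.any():
        t = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        out[m] = b[m] + t[:, None] * (c[m] - b[m])
        done |= m
    # interior
    m = ~done
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
        v = vb[m] / denom
        w = vc[m] / denom
        out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class SurfaceLocator:
    """Accelerated exact closest-point queries against one triangular mesh.

    A vertex KD-tree yields an upper bound on the surface distance for each
    query; a face-centroid KD-tree then enumerates every triangle that could
    beat that bound, and the exact point-triangle minimum is taken over the
    candidates.  Results equal brute force over all triangles.
    """

    def __init__(self, mesh: TriMesh):
        if mesh.n_faces == 0:
            raise ValueError("mesh has no faces")
        self.mesh = mesh
        self._tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self._centroids = self._tri.mean(axis=1)
        self._radii = np.linalg.norm(self._tri - self._centroids[:, None], axis=2).max(axis=1)
        self._rmax = float(self._radii.max())
        self._vtree = cKDTree(mesh.vertices)
        self._ctree = cKDTree(self._centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest surface points for (n, 3) queries.

        Returns (feet (n, 3), distances (n,), face indices (n,)).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ub, _ = self._vtree.query(pts)
        # any triangle whose centroid ball cannot reach below ub is pruned
        lists = self._ctree.query_ball_point(pts, ub + self._rmax + 1e-12)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
        flat_faces = np.fromiter(
            (f for l in lists for f in l), dtype=np.int64, count=int(counts.sum())
        )
        flat_pts = np.repeat(pts, counts, axis=0)
        tri = self._tri[flat_faces]
        feet = _point_triangle_closest(flat_pts, tri[:, 0], tri[:, 1], tri[:, 2])
        d = np.linalg.norm(feet - flat_pts, axis=1)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        out_feet = np.empty_like(pts)
        out_d = np.empty(len(pts))
        out_face = np.empty(len(pts), dtype=np.int64)
        for i in range(len(pts)):
            lo, hi = offsets[i], offsets[i + 1]
            if lo == hi:  # cannot happen: the nearest vertex's faces qualify
                raise RuntimeError("no candidate triangles")
            j = lo + int(np.argmin(d[lo:hi]))
            out_feet[i] = feet[j]
            out_d[i] = d[j]
            out_face[i] = flat_faces[j]
        return out_feet, out_d, out_face


def closest_point_on_mesh(
    query: np.ndarray, mesh: TriMesh
) -> tuple[np.ndarray, float, int]:
    """Exact closest point on the mesh surface to one 3D query point.

    Returns (foot point, distance in mm, face index).
    """
    loc = SurfaceLocator(mesh)
    feet, d, f = loc.query(np.asarray(query, dtype=float).reshape(1, 3))
    return feet[0], float(d[0]), int(f[0])


# ---------------------------------------------------------------------------
# Elastic ICP
# ---------------------------------------------------------------------------


@dataclass
class ICPParams:
    """Elastic-ICP control parameters.

    sigma_schedule: Gaussian smoothing bandwidths (mm), one per iteration,
    non-increasing.  correspondence_mode is "surface" (nearest point on the
    target surface) or "vertex" (nearest target vertex).  stochastic_fraction
    < 1 resamples only that fraction of correspondences each iteration,
    which is the toolkit's declared source of run-to-run variability.
    """

    sigma_schedule: Sequence[float]
    step_fraction: float = 0.5
    max_displacement: float = 10.0
    correspondence_mode: str = "surface"
    stochastic_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sigma_schedule = [float(s) for s in self.sigma_schedule]
        if not self.sigma_schedule:
            raise ValueError("sigma_schedule must be non-empty")
        if any(s <= 0 for s in self.sigma_schedule):
            raise ValueError("all sigmas must be > 0")
        if np.any(np.diff(self.sigma_schedule) > 1e-12):
            raise ValueError("sigma_schedule must be non-increasing")
        if not (0 < self.step_fraction <= 1):
            raise ValueError("step_fraction must be in (0, 1]")
        if not (0 < self.stochastic_fraction <= 1):
            raise ValueError("stochastic_fraction must be in (0, 1]")
        if self.correspondence_mode not in ("surface", "vertex"):
            raise ValueError("correspondence_mode must be 'surface' or 'vertex'")

    @property
    def n_iterations(self) -> int:
        return len(self.sigma_schedule)

    def replace_seed(self, seed: int) -> "ICPParams":
        return ICPParams(
            sigma_schedule=list(self.sigma_schedule),
            step_fraction=self.step_fraction,
            max_displacement=self.max_displacement,
            correspondence_mode=self.correspondence_mode,
            stochastic_fraction=self.stochastic_fraction,
            seed=int(seed),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ICPParams":
        return cls(**d)


def default_icp_params(
    reference: TriMesh,
    n_iterations: int = 40,
    *,
    sigma_start_factor: float = 10.0,
    sigma_end_factor: float = 0.5,
    stochastic_fraction: float = 1.0,
    correspondence_mode: str = "surface",
    seed: int = 0,
) -> ICPParams:
    """Defaults scaled to the reference mesh: sigma decays geometrically from
    ``sigma_start_factor`` to ``sigma_end_factor`` times the mean edge length;
    displacement cap is 5 edge lengths."""
    e = mean_edge_length(reference)
    schedule = e * np.geomspace(sigma_start_factor, sigma_end_factor, n_iterations)
    return ICPParams(
        sigma_schedule=schedule.tolist(),
        step_fraction=0.5,
        max_displacement=5.0 * e,
        correspondence_mode=correspondence_mode,
        stochastic_fraction=stochastic_fraction,
        seed=seed,
    )


def _smooth_displacements(
    vertices: np.ndarray, disp: np.ndarray, sigma: float
) -> np.ndarray:
    """Gaussian-kernel smoothing of a per-vertex displacement field over
    Euclidean inter-vertex distances, truncated at 3 sigma, rows normalized."""
    d2 = cdist(vertices, vertices, metric="sqeuclidean")
    w = np.exp(-0.5 * d2 / (sigma * sigma))
    w[d2 > (3.0 * sigma) ** 2] = 0.0
    np.fill_diagonal(w, np.maximum(w.diagonal(), 1e-300))
    w /= w.sum(axis=1, keepdims=True)
    return w @ disp


def elastic_icp(
    reference: TriMesh, target: TriMesh, params: ICPParams
) -> tuple[TriMesh, np.ndarray]:
    """Deform the (pre-aligned) reference onto the target.

    Returns the deformed copy of the reference (identical topology) and the
    per-iteration mean correspondence distance trace.
    """
    V = reference.vertices.copy()
    n = len(V)
    if params.correspondence_mode == "surface":
        locator = SurfaceLocator(target)

        def closest(pts: np.ndarray) -> np.ndarray:
            return locator.query(pts)[0]

    else:
        tree = cKDTree(target.vertices)

        def closest(pts: np.ndarray) -> np.ndarray:
            _, idx = tree.query(pts)
            return target.vertices[idx]

    rng = np.random.default_rng(params.seed)
    corr = closest(V)
    trace = np.empty(params.n_iterations)
    for it, sigma in enumerate(params.sigma_schedule):
        if it > 0:
            if params.stochastic_fraction >= 1.0:
                corr = closest(V)
            else:
                k = max(1, int(round(params.stochastic_fraction * n)))
                idx = rng.choice(n, size=k, replace=False)
                corr[idx] = closest(V[idx])
        disp = corr - V
        trace[it] = float(np.linalg.norm(disp, axis=1).mean())
        sm = _smooth_displacements(V, disp, float(sigma))
        norms = np.linalg.norm(sm, axis=1)
        over = norms > params.max_displacement
        if over.any():
            sm[over] *= (params.max_displacement / norms[over])[:, None]
        V = V + params.step_fraction * sm
    return reference.with_vertices(V), trace


# ---------------------------------------------------------------------------
# Whole-sample registration
# ---------------------------------------------------------------------------


@dataclass
class RegisteredSample:
    """Dense corresponding coordinates for a whole sample.

    coordinates has shape (specimens, vertices, 3); faces are the reference
    faces (dropped after subsampling).  seeds are the per-specimen ICP seeds.
    """

    reference_id: str
    specimen_ids: list[str]
    coordinates: np.ndarray
    faces: np.ndarray | None
    subsample_indices: np.ndarray | None = None
    seeds: list[int] = field(default_factory=list)
    params: ICPParams | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (specimens, vertices, 3)")
        if self.coordinates.shape[0] != len(self.specimen_ids):
            raise ValueError("specimen count mismatch")

    @property
    def n_specimens(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[1]

    @property
    def is_subsampled(self) -> bool:
        return self.subsample_indices is not None

    def index_of(self, specimen_id: str) -> int:
        try:
            return self.specimen_ids.index(specimen_id)
        except ValueError as exc:
            raise KeyError(f"unknown specimen '{specimen_id}'") from exc

    def specimen_mesh(self, specimen_id: str) -> TriMesh:
        """Deformed-reference mesh of one specimen (requires faces)."""
        if self.faces is None:
            raise ValueError("sample has no face topology (subsampled)")
        return TriMesh(specimen_id, self.coordinates[self.index_of(specimen_id)], self.faces)

    # -- persistence (text formats only) -----------------------------------

    def save_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(self.specimen_ids):
            arr = self.coordinates[i]
            with open(path / f"coords_{i:04d}.csv", "w") as fh:
                fh.write("vertex_index,x,y,z\n")
                for j, (x, y, z) in enumerate(arr):
                    fh.write(f"{j},{x:.17g},{y:.17g},{z:.17g}\n")
        manifest = {
            "reference_id": self.reference_id,
            "specimen_ids": self.specimen_ids,
            "n_vertices": int(self.n_vertices),
            "faces": None if self.faces is None else self.faces.tolist(),
            "subsample_indices": None
            if self.subsample_indices is None
            else [int(v) for v in self.subsample_indices],
            "seeds": [int(s) for s in self.seeds],
            "params": None if self.params is None else self.params.to_dict(),
        }
        (path / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load_dir(cls, path: str | Path) -> "RegisteredSample":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        coords = []
        for i in range(len(manifest["specimen_ids"])):
            rows = np.loadtxt(path / f"coords_{i:04d}.csv", delimiter=",", skiprows=1)
            coords.append(rows[:, 1:4])
        return cls(
            reference_id=manifest["reference_id"],
            specimen_ids=list(manifest["specimen_ids"]),
            coordinates=np.stack(coords),
            faces=None if manifest["faces"] is None else np.asarray(manifest["faces"], dtype=np.int64),
            subsample_indices=None
            if manifest["subsample_indices"] is None
            else np.asarray(manifest["subsample_indices"], dtype=np.int64),
            seeds=list(manifest["seeds"]),
            params=None if manifest["params"] is None else ICPParams.from_dict(manifest["params"]),
        )


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


def register_sample(
    reference: TriMesh,
    reference_lms: LandmarkSet,
    targets: Sequence[tuple[TriMesh, LandmarkSet]],
    params: ICPParams,
    k: int | None = None,
    *,
    include_reference: bool = True,
    validate: bool = True,
) -> RegisteredSample:
    """Register the reference onto every target: TPS on the six landmarks,
    then elastic ICP.  The reference enters as an (undeformed) specimen.

    If ``k`` is given, the dense correspondence is reduced to k vertices by
    k-means subsampling (clustering on the reference configuration).
    """
    reference_lms.require_registration_landmarks()
    if validate:
        report = validate_single_layer(reference)
        if not report.passed:
            raise ValueError(f"reference '{reference.specimen_id}' failed validation")
        for mesh, _ in targets:
            rep = validate_single_layer(mesh)
            if not rep.passed:
                raise ValueError(f"target '{mesh.specimen_id}' failed validation")
    for _, lms in targets:
        lms.require_registration_landmarks()

    seeds = _derive_seeds(params.seed, len(targets))
    coords = []
    ids = []
    if include_reference:
        coords.append(reference.vertices.copy())
        ids.append(reference.specimen_id)
    for i, (mesh, lms) in enumerate(targets):
        warp = tps_fit(reference_lms, lms)
        pre = reference.with_vertices(tps_apply(warp, reference.vertices))
        deformed, _ = elastic_icp(pre, mesh, params.replace_seed(seeds[i]))
        coords.append(deformed.vertices)
        ids.append(mesh.specimen_id)

    sample = RegisteredSample(
        reference_id=reference.specimen_id,
        specimen_ids=ids,
        coordinates=np.stack(coords),
        faces=reference.faces.copy(),
        seeds=seeds,
        params=params,
    )
    if k is not None:
        from .subsampling import subsample_registered

        sample = subsample_registered(sample, k, seed=params.seed)
    return sample
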