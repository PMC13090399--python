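"""Synthetic cranial-patch generator.

Builds frontal-bone-like open surface patches from an analytic parametric
surface so that ground-truth dense correspondence between any two shapes is
known by parameter value.  This is what enables oracle tests of the
registration pipeline: two patches generated at the same (u, v) grid
correspond vertex-by-vertex, and a target surface can be evaluated at the
reference's parameters to obtain the true matching points.

Geometry: a half-ellipsoid cap (the vertical squama) with a Gaussian ridge
along its anterior-inferior margin (brow prominence), sheared posteriorly by
an inclination factor, and scaled globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh_io import REQUIRED_LANDMARKS, LandmarkSet, TriMesh

__all__ = [
    "ShapeParams",
    "GroupSpec",
    "PopulationSpec",
    "surface_point",
    "make_template",
    "template_landmarks",
    "sample_population",
    "perturb_landmarks",
]

# Parametric positions (u, v) of the six canonical landmarks on the patch.
# u in [0, 1] runs inferior -> superior (brow to apex); v in [-1, 1] left -> right.
_LANDMARK_UV = {
    "bregma": (1.0, 0.0),
    "ophryon": (0.25, 0.0),
    "frontotemporale_L": (0.10, -1.0),
    "frontotemporale_R": (0.10, 1.0),
    "stephanion_L": (0.65, -1.0),
    "stephanion_R": (0.65, 1.0),
}

_RIDGE_U = 0.10       # parametric centre of the brow ridge
_RIDGE_WIDTH = 0.07   # Gaussian sigma in u


@dataclass
class ShapeParams:
    """Shape-controlling parameters of the synthetic patch.

    squama_inclination in [0, 1]: 0 = vertical squama, 1 = strongly receding.
    brow_prominence (mm): amplitude of the anterior supraorbital bulge.
    squama_breadth: lateral aspect factor (1 = reference proportions).
    size_scale: global similarity scale (> 0).
    """

    squama_inclination: float = 0.3
    brow_prominence: float = 2.0
    squama_breadth: float = 1.0
    size_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.brow_prominence < 0:
            raise ValueError("brow_prominence must be >= 0")
        if self.size_scale <= 0:
            raise ValueError("size_scale must be > 0")


def _sd_params(
    squama_inclination=0.05, brow_prominence=0.3, squama_breadth=0.03, size_scale=0.05
) -> ShapeParams:
    """Per-parameter SDs, reusing the ShapeParams container (bypasses the
    mean-value invariants, which do not apply to spreads)."""
    sd = ShapeParams.__new__(ShapeParams)
    sd.squama_inclination = squama_inclination
    sd.brow_prominence = brow_prominence
    sd.squama_breadth = squama_breadth
    sd.size_scale = size_scale
    return sd


@dataclass
class GroupSpec:
    label: str
    mean: ShapeParams
    sd: ShapeParams = field(default_factory=_sd_params)
    n: int = 10

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group n must be >= 1")


@dataclass
class PopulationSpec:
    """Sampling plan for a group-structured synthetic population."""

    groups: list[GroupSpec]
    allometric_slope: float = 0.0  # change in squama_inclination per unit log size
    landmark_noise_sd: float = 0.0  # mm
    vertex_jitter_sd: float = 0.0  # mm
    mesh_resolution: int = 400  # target vertex count
    resolution_spread: float = 0.1  # per-specimen re-triangulation +-fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.landmark_noise_sd < 0 or self.vertex_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for g in self.groups:
            for attr in ("squama_inclination", "brow_prominence", "squama_breadth", "size_scale"):
                if getattr(g.sd, attr) < 0:
                    raise ValueError(f"group '{g.label}': SD of {attr} must be >= 0")


def surface_point(params: ShapeParams, u, v) -> np.ndarray:
    """Evaluate the analytic patch at parameters (u, v).

    Accepts scalars or broadcastable arrays; returns (..., 3).  The map is the
    ground-truth correspondence between any two parameter sets.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    a = 60.0 * params.squama_breadth  # lateral semi-axis, mm
    b = 50.0                          # anterior semi-axis, mm
    c = 70.0                          # vertical semi-axis, mm
    alpha = u * np.radians(78.0)      # elevation from anterior margin to apex
    beta = v * np.radians(55.0)       # lateral azimuth
    x = a * np.cos(alpha) * np.sin(beta)
    y = b * np.cos(alpha) * np.cos(beta)
    z = c * np.sin(alpha)
    # supraorbital ridge: outward bulge localized in a band around _RIDGE_U
    bump = params.brow_prominence * np.exp(-0.5 * ((u - _RIDGE_U) / _RIDGE_WIDTH) ** 2)
    x = x + bump * np.sin(beta)
    y = y + bump * np.cos(beta)
    # receding squama: shear anterior coordinate down with height
    y = y - params.squama_inclination * 0.6 * z
    return params.size_scale * np.stack(
        np.broadcast_arrays(x, y, z), axis=-1
    )


def _grid_shape(resolution: int) -> tuple[int, int]:
    # patch is taller than wide in parameter space; nv kept odd so the
    # midline v = 0 is an actual vertex column
    nu = max(5, int(round(np.sqrt(resolution * 1.3))))
    nv = max(5, int(round(resolution / nu)))
    if nv % 2 == 0:
        nv += 1
    return nu, nv


def template_landmarks(params: ShapeParams, specimen_id: str = "template") -> LandmarkSet:
    """Noise-free landmarks at their canonical parametric positions."""
    pts = {
        name: surface_point(params, *_LANDMARK_UV[name]) for name in REQUIRED_LANDMARKS
    }
    return LandmarkSet(specimen_id, pts)


def make_template(
    params: ShapeParams, resolution: int = 400, specimen_id: str = "template"
) -> tuple[TriMesh, LandmarkSet]:
    """Triangulate the parametric patch at roughly ``resolution`` vertices.

    Deterministic for fixed inputs.  Vertices are laid out row-major over the
    (u, v) grid, so two templates with the same resolution correspond
    vertex-by-vertex.
    """
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    nu, nv = _grid_shape(resolution)
    u = np.linspace(0.0, 1.0, nu)
    v = np.linspace(-1.0, 1.0, nv)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    verts = surface_point(params, uu.ravel(), vv.ravel())
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            q = i * nv + j
            faces.append([q, q + nv, q + 1])
            faces.append([q + 1, q + nv, q + nv + 1])
    mesh = TriMesh(specimen_id, verts, np.asarray(faces, dtype=np.int64))
    return mesh, template_landmarks(params, specimen_id)


def grid_uv(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """The (u, v) parameters of each vertex of ``make_template`` at this
    resolution, row-major — the ground-truth correspondence key."""
    nu, nv = _grid_shape(resolution)
    uu, vv = np.meshgrid(
        np.linspace(0.0, 1.0, nu), np.linspace(-1.0, 1.0, nv), indexing="ij"
    )
    return uu.ravel(), vv.ravel()


def _draw_params(group: GroupSpec, rng: np.random.Generator) -> ShapeParams:
    def draw(mean, sd, lo=None):
        val = rng.normal(mean, sd) if sd > 0 else mean
        if lo is not None:
            val = max(lo, val)
        return float(val)

    p = ShapeParams.__new__(ShapeParams)
    p.squama_inclination = draw(group.mean.squama_inclination, group.sd.squama_inclination)
    p.brow_prominence = draw(group.mean.brow_prominence, group.sd.brow_prominence, lo=0.0)
    p.squama_breadth = draw(group.mean.squama_breadth, group.sd.squama_breadth, lo=0.1)
    p.size_scale = draw(group.mean.size_scale, group.sd.size_scale, lo=0.05)
    return p


def sample_population(
    spec: PopulationSpec,
) -> tuple[list[TriMesh], list[LandmarkSet], pd.DataFrame]:
    """Draw a seed-reproducible population of meshes + landmarks + study table.

    Per specimen: shape parameters are drawn from the group distribution,
    squama_inclination is coupled to the drawn log size via
    ``allometric_slope``, the template is built at a perturbed resolution
    (independent re-triangulation), vertices are jittered, and landmarks are
    perturbed isotropically.
    """
    rng = np.random.default_rng(spec.seed)
    meshes: list[TriMesh] = []
    landmark_sets: list[LandmarkSet] = []
    rows = []
    idx = 0
    for group in spec.groups:
        log_mean_size = np.log(group.mean.size_scale)
        for _ in range(group.n):
            sid = f"{group.label}_{idx:03d}"
            p = _draw_params(group, rng)
            log_size = np.log(p.size_scale)
            p.squama_inclination += spec.allometric_slope * (log_size - log_mean_size)
            if spec.resolution_spread > 0:
                res = int(
                    round(
                        spec.mesh_resolution
                        * (1.0 + rng.uniform(-spec.resolution_spread, spec.resolution_spread))
                    )
                )
            else:
                res = spec.mesh_resolution
            res = max(50, res)
            mesh, lms = make_template(p, res, specimen_id=sid)
            if spec.vertex_jitter_sd > 0:
                mesh = mesh.with_vertices(
                    mesh.vertices
                    + rng.normal(0.0, spec.vertex_jitter_sd, mesh.vertices.shape)
                )
            if spec.landmark_noise_sd > 0:
                lms = LandmarkSet(
                    sid,
                    {
                        k: pt + rng.normal(0.0, spec.landmark_noise_sd, 3)
                        for k, pt in lms.points.items()
                    },
                )
            meshes.append(mesh)
            landmark_sets.append(lms)
            rows.append(
                {
                    "specimen_id": sid,
                    "group": group.label,
                    "period": group.label,
                    "abbreviation": f"{group.label[:2]}{idx}",
                    "squama_inclination": p.squama_inclination,
                    "brow_prominence": p.brow_prominence,
                    "squama_breadth": p.squama_breadth,
                    "size_scale": p.size_scale,
                    "log_size": log_size,
                    "resolution": res,
                }
            )
            idx += 1
    return meshes, landmark_sets, pd.DataFrame(rows)


def perturb_landmarks(
    lms: LandmarkSet, sd: float, n_repeats: int, seed: int = 0
) -> list[LandmarkSet]:
    """Simulated repeated digitization: isotropic Gaussian noise per landmark.

    Repeats are tagged with synthetic observer/session ids (two sessions per
    synthetic observer) so the error toolkit can classify intra vs inter.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_repeats):
        pts = {
            k: p + (rng.normal(0.0, sd, 3) if sd > 0 else 0.0)
            for k, p in lms.points.items()
        }
        out.append(
            LandmarkSet(
                lms.specimen_id,
                pts,
                observer_id=f"obs{r // 2 + 1}",
                session_id=f"s{r % 2 + 1}",
            )
        )
    return out
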