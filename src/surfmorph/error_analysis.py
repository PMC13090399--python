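"""Observer-error quantification and its propagation to registered meshes.

Landmark placement error is summarized as Euclidean distances between
repeated digitizations (intra- vs inter-observer by metadata); registration
error is summarized over all corresponding vertex pairs of repeatedly
registered meshes, with an exceedance threshold and per-vertex mean
displacement fields for heat maps.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mesh_io import LandmarkSet, TriMesh, save_ply

__all__ = [
    "LandmarkErrorTable",
    "CorrespondenceErrorReport",
    "landmark_error",
    "correspondence_error",
    "surface_error",
    "export_heatmap",
]


@dataclass
class LandmarkErrorTable:
    """All pairwise repeat-to-repeat landmark distances plus a per-landmark
    summary (min/max/mean, mm)."""

    table: pd.DataFrame  # landmark, kind, set_a, set_b, distance_mm
    summary: pd.DataFrame  # landmark, min, max, mean


@dataclass
class CorrespondenceErrorReport:
    """Displacement statistics over all mesh pairs x corresponding vertices."""

    n_pairs_total: int
    n_exceeding: int
    threshold_mm: float
    mean_displacement: float
    per_vertex_mean: np.ndarray
    percent_exceeding: float = field(init=False)

    def __post_init__(self) -> None:
        self.percent_exceeding = 100.0 * self.n_exceeding / self.n_pairs_total

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_pairs_total": self.n_pairs_total,
                "n_exceeding": self.n_exceeding,
                "threshold_mm": self.threshold_mm,
                "percent_exceeding": self.percent_exceeding,
                "mean_displacement": self.mean_displacement,
            }
        )


def _set_label(lms: LandmarkSet) -> str:
    return f"{lms.observer_id or 'obs?'}/{lms.session_id or 's?'}"


def landmark_error(repeats: Sequence[LandmarkSet]) -> LandmarkErrorTable:
    """Euclidean distances between all pairs of repeated landmark sets.

    Rows are labeled "intra" when both repeats share an observer_id and
    "inter" otherwise.  All sets must name the same landmarks and specimen.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeated landmark sets")
    names = set(repeats[0].names)
    for lms in repeats[1:]:
        if set(lms.names) != names:
            raise ValueError("repeated landmark sets name different landmarks")
        if lms.specimen_id != repeats[0].specimen_id:
            raise ValueError("repeats must belong to one specimen")
    order = repeats[0].names
    rows = []
    for a, b in itertools.combinations(repeats, 2):
        kind = (
            "intra"
            if a.observer_id is not None and a.observer_id == b.observer_id
            else "inter"
        )
        for name in order:
            rows.append(
                {
                    "landmark": name,
                    "kind": kind,
                    "set_a": _set_label(a),
                    "set_b": _set_label(b),
                    "distance_mm": float(np.linalg.norm(a.points[name] - b.points[name])),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("landmark", sort=False)["distance_mm"]
        .agg(["min", "max", "mean"])
        .reset_index()
    )
    return LandmarkErrorTable(table, summary)


def correspondence_error(
    meshes: Sequence[TriMesh | np.ndarray], threshold: float = 1.0
) -> CorrespondenceErrorReport:
    """Displacements between corresponding vertices over all unordered mesh
    pairs; total combinations = (#pairs) x (#vertices)."""
    if len(meshes) < 2:
        raise ValueError("need at least 2 registered meshes")
    arrays = [
        m.vertices if isinstance(m, TriMesh) else np.asarray(m, dtype=float)
        for m in meshes
    ]
    n_vertices = len(arrays[0])
    for a in arrays[1:]:
        if len(a) != n_vertices:
            raise ValueError("vertex count mismatch between registered meshes")
    per_vertex_sum = np.zeros(n_vertices)
    n_exceeding = 0
    total_disp = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(arrays, 2):
        d = np.linalg.norm(a - b, axis=1)
        per_vertex_sum += d
        n_exceeding += int((d > threshold).sum())
        total_disp += float(d.sum())
        n_pairs += 1
    n_total = n_pairs * n_vertices
    return CorrespondenceErrorReport(
        n_pairs_total=n_total,
        n_exceeding=n_exceeding,
        threshold_mm=threshold,
        mean_displacement=total_disp / n_total,
        per_vertex_mean=per_vertex_sum / n_pairs,
    )


def surface_error(
    meshes: Sequence[TriMesh], threshold: float = 1.0
) -> CorrespondenceErrorReport:
    """Like :func:`correspondence_error` but measuring each vertex's distance
    to the *surface* of the other mesh of the pair, not to its corresponding
    vertex.

    This is the quantity heat maps visualize: vertices of two registrations
    that both lie on the target surface score ~0 even if they slid
    tangentially, so residual error concentrates where the meshes genuinely
    diverge (typically the free boundary).  Each unordered pair contributes
    one combination per vertex (the two directed distances are averaged).
    """
    if len(meshes) < 2:
        raise ValueError("need at least 2 registered meshes")
    n_vertices = meshes[0].n_vertices
    for m in meshes[1:]:
        if m.n_vertices != n_vertices:
            raise ValueError("vertex count mismatch between registered meshes")
    from .registration import SurfaceLocator

    locators = [SurfaceLocator(m) for m in meshes]
    per_vertex_sum = np.zeros(n_vertices)
    n_exceeding = 0
    total = 0.0
    n_pairs = 0
    for (i, a), (j, b) in itertools.combinations(enumerate(meshes), 2):
        d = 0.5 * (locators[j].query(a.vertices)[1] + locators[i].query(b.vertices)[1])
        per_vertex_sum += d
        n_exceeding += int((d > threshold).sum())
        total += float(d.sum())
        n_pairs += 1
    n_total = n_pairs * n_vertices
    return CorrespondenceErrorReport(
        n_pairs_total=n_total,
        n_exceeding=n_exceeding,
        threshold_mm=threshold,
        mean_displacement=total / n_total,
        per_vertex_mean=per_vertex_sum / n_pairs,
    )


def export_heatmap(
    mesh: TriMesh,
    field_values: np.ndarray,
    path: str | Path,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Write the mesh as PLY with the scalar field as per-vertex quality and
    an RGB ramp; colormap limits go to a JSON sidecar."""
    field_values = np.asarray(field_values, dtype=float)
    if len(field_values) != mesh.n_vertices:
        raise ValueError("field length does not match vertex count")
    import matplotlib

    lo = float(field_values.min()) if vmin is None else float(vmin)
    hi = float(field_values.max()) if vmax is None else float(vmax)
    span = hi - lo
    normed = np.zeros_like(field_values) if span <= 0 else (field_values - lo) / span
    rgba = matplotlib.colormaps[cmap](np.clip(normed, 0.0, 1.0))
    colors = (rgba[:, :3] * 255).astype(np.uint8)
    path = Path(path)
    save_ply(
        mesh,
        path,
        binary=False,
        vertex_attributes={
            "quality": field_values,
            "red": colors[:, 0],
            "green": colors[:, 1],
            "blue": colors[:, 2],
        },
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"cmap": cmap, "vmin": lo, "vmax": hi}))
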