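"""k-means vertex subsampling of a dense registered sample.

Vertices of the reference configuration are partitioned into k clusters; the
actual mesh vertex closest to each cluster mean is kept (never a synthetic
centroid), and the selected indices are broadcast to every specimen so
correspondence is preserved.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .registration import RegisteredSample

__all__ = [
    "SubsampleSelection",
    "kmeans_partition",
    "select_representatives",
    "subsample_registered",
]


@dataclass
class SubsampleSelection:
    """Outcome of one k-means subsampling: which reference vertices survive."""

    k: int
    vertex_indices: np.ndarray  # sorted, unique
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)
        if len(np.unique(self.vertex_indices)) != self.k:
            raise ValueError("vertex_indices must be k unique indices")

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "vertex_indices": [int(v) for v in self.vertex_indices],
                "inertia": self.inertia,
                "seed": self.seed,
            }
        )


def kmeans_partition(
    points: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means, best restart by inertia.

    Restarts use k-means++ seeding; for tiny inputs (few enough k-subsets of
    points) Lloyd is instead started once from every distinct k-subset, which
    in practice reaches the global optimum there.  Returns (assignments (n,),
    centroids (k, d), inertia).
    """
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    n = len(pts)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return np.arange(n), pts.copy(), 0.0
    if math.comb(n, k) <= max(200, n_restarts):
        best = None
        for subset in itertools.combinations(range(n), k):
            km = KMeans(n_clusters=k, init=pts[list(subset)], n_init=1, max_iter=300).fit(pts)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        km = best
    else:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            max_iter=300,
            random_state=seed % (2**32),
        ).fit(pts)
    return km.labels_.astype(np.int64), km.cluster_centers_, float(km.inertia_)


def select_representatives(
    points: np.ndarray,
    assignments: np.ndarray,
    centroids: np.ndarray,
    seed: int = 0,
) -> SubsampleSelection:
    """For each cluster keep the member vertex nearest its mean (ties break
    to the lowest vertex index)."""
    pts = np.asarray(points, dtype=float)
    assignments = np.asarray(assignments)
    k = len(centroids)
    reps = np.empty(k, dtype=np.int64)
    inertia = 0.0
    for c in range(k):
        members = np.nonzero(assignments == c)[0]
        if members.size == 0:
            raise RuntimeError(f"cluster {c} is empty")
        d2 = np.sum((pts[members] - centroids[c]) ** 2, axis=1)
        reps[c] = members[int(np.argmin(d2))]  # argmin takes first == lowest index
        inertia += float(d2.sum())
    return SubsampleSelection(
        k=k, vertex_indices=np.sort(reps), inertia=inertia, seed=seed
    )


def subsample_registered(
    sample: RegisteredSample, k: int, seed: int = 0, n_restarts: int = 10
) -> RegisteredSample:
    """Reduce a dense RegisteredSample to k corresponding vertices.

    Clustering runs once, on the reference specimen's configuration; the
    selected vertex indices are applied to every specimen, so the subsample
    stays in correspondence.  Faces are dropped.
    """
    if sample.is_subsampled:
        raise ValueError("sample is already subsampled")
    if not (1 <= k <= sample.n_vertices):
        raise ValueError(f"k must be in [1, {sample.n_vertices}], got {k}")
    try:
        ref_row = sample.index_of(sample.reference_id)
    except KeyError:
        ref_row = 0
    ref_pts = sample.coordinates[ref_row]
    labels, centers, _ = kmeans_partition(ref_pts, k, seed=seed, n_restarts=n_restarts)
    selection = select_representatives(ref_pts, labels, centers, seed=seed)
    idx = selection.vertex_indices
    return RegisteredSample(
        reference_id=sample.reference_id,
        specimen_ids=list(sample.specimen_ids),
        coordinates=sample.coordinates[:, idx, :].copy(),
        faces=None,
        subsample_indices=idx,
        seeds=list(sample.seeds),
        params=sample.params,
    )
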