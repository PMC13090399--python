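"""Optimal-subsample determination protocol.

Repeated registrations of the same dataset are compared through the
correlation of their PC-score distance structures: one reference iteration
(no subsampling), several more unsubsampled iterations spanning a baseline
envelope, and one iteration per candidate subsample size k.  The smallest k
whose correlation reaches the baseline minimum is the optimal subsample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .mesh_io import LandmarkSet, TriMesh
from .registration import ICPParams, register_sample
from .shape_stats import gpa, pca_shape

__all__ = [
    "IterationRecord",
    "OptimizationResult",
    "pc_distance_vector",
    "iteration_correlation",
    "run_optimization",
    "choose_optimal_k",
    "DEFAULT_K_LADDER",
]

DEFAULT_K_LADDER = (25, 50, 100, 150, 200, 250, 500, 1000, 2500, 5000)


@dataclass
class IterationRecord:
    """One pipeline iteration: registration -> (subsample) -> GPA -> PCA."""

    iteration_id: str
    k: int | None
    seed: int
    pc_scores: np.ndarray
    distance_vector: np.ndarray
    r_vs_reference: float | None = None


@dataclass
class OptimizationResult:
    """Baseline envelope plus the per-k correlation curve."""

    baseline_r: list[float]
    k_values: list[int]
    k_r: dict[int, float]
    records: list[IterationRecord] = field(default_factory=list)

    @property
    def baseline_r_min(self) -> float:
        return min(self.baseline_r)

    @property
    def baseline_r_max(self) -> float:
        return max(self.baseline_r)

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_r": self.baseline_r,
                "baseline_r_min": self.baseline_r_min,
                "baseline_r_max": self.baseline_r_max,
                "k_r": {str(k): v for k, v in self.k_r.items()},
                "chosen_k": choose_optimal_k(self),
            }
        )


def pc_distance_vector(pc_scores: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between specimen score rows (all
    components), condensed in row-major (i < j) order."""
    scores = np.asarray(pc_scores, dtype=float)
    if scores.ndim != 2 or len(scores) < 2:
        raise ValueError("need a (specimens >= 2, components) score matrix")
    return pdist(scores)


def iteration_correlation(a: IterationRecord | np.ndarray, b: IterationRecord | np.ndarray) -> float:
    """Pearson correlation of two iterations' distance vectors."""
    va = a.distance_vector if isinstance(a, IterationRecord) else np.asarray(a, dtype=float)
    vb = b.distance_vector if isinstance(b, IterationRecord) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("distance vectors have different lengths")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("zero-variance distance vector: correlation undefined")
    if np.array_equal(va, vb):  # identical iterations correlate exactly
        return 1.0
    return float(pearsonr(va, vb)[0])


def _one_iteration(
    iteration_id: str,
    reference: TriMesh,
    reference_lms: LandmarkSet,
    targets: Sequence[tuple[TriMesh, LandmarkSet]],
    params: ICPParams,
    k: int | None,
    seed: int,
    include_reference: bool,
) -> IterationRecord:
    sample = register_sample(
        reference,
        reference_lms,
        targets,
        params.replace_seed(seed),
        k=k,
        include_reference=include_reference,
        validate=False,
    )
    space = pca_shape(gpa(sample))
    return IterationRecord(
        iteration_id=iteration_id,
        k=k,
        seed=seed,
        pc_scores=space.pc_scores,
        distance_vector=pc_distance_vector(space.pc_scores),
    )


def run_optimization(
    reference: TriMesh,
    reference_lms: LandmarkSet,
    targets: Sequence[tuple[TriMesh, LandmarkSet]],
    params: ICPParams,
    k_ladder: Sequence[int] | None = None,
    n_baseline: int = 16,
    seed: int = 0,
    include_reference: bool = True,
) -> OptimizationResult:
    """Run the whole protocol on one dataset.

    For run-to-run variability the registration should be configured with
    ``stochastic_fraction < 1``; in fully deterministic mode every baseline
    correlation is exactly 1.
    """
    n_vertices = reference.n_vertices
    if k_ladder is None:
        k_ladder = [k for k in DEFAULT_K_LADDER if k <= n_vertices]
    else:
        for k in k_ladder:
            if k > n_vertices:
                raise ValueError(f"ladder k={k} exceeds vertex count {n_vertices}")
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(1 + n_baseline + len(k_ladder))]

    def iterate(iid, k, s):
        return _one_iteration(
            iid, reference, reference_lms, targets, params, k, s, include_reference
        )

    reference_it = iterate("reference", None, seeds[0])
    records = [reference_it]
    baseline_r = []
    for b in range(n_baseline):
        rec = iterate(f"baseline_{b}", None, seeds[1 + b])
        rec.r_vs_reference = iteration_correlation(rec, reference_it)
        baseline_r.append(rec.r_vs_reference)
        records.append(rec)
    k_r = {}
    for j, k in enumerate(k_ladder):
        kk = None if k >= n_vertices else int(k)
        rec = iterate(f"k_{k}", kk, seeds[1 + n_baseline + j])
        rec.k = int(k)
        rec.r_vs_reference = iteration_correlation(rec, reference_it)
        k_r[int(k)] = rec.r_vs_reference
        records.append(rec)
    return OptimizationResult(
        baseline_r=baseline_r, k_values=[int(k) for k in k_ladder], k_r=k_r, records=records
    )


def choose_optimal_k(result: OptimizationResult) -> int | None:
    """Smallest k whose correlation reaches the baseline minimum, or None if
    no candidate qualifies."""
    acceptable = [k for k, r in result.k_r.items() if r >= result.baseline_r_min]
    return min(acceptable) if acceptable else None
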