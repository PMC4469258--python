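"""Diversity selection (MaxMin) and k-means partitioning over fingerprint
Tanimoto distance.

MaxMin picks, at every step, the candidate whose minimum distance to the
already-picked set is maximal (ties broken by lowest index), so the sequence
of pick radii is non-increasing.  k-means uses real-valued centroids (the
component-wise mean of member bit vectors) with the continuous Tanimoto
coefficient

    T(x, c) = sum(x_i c_i) / (sum(x_i^2) + sum(c_i^2) - sum(x_i c_i)),

which reduces exactly to the binary coefficient on bit vectors.  The
objective is the sum over compounds of (1 - T to own centroid); iterations
that would increase it are rolled back, so the recorded objective history is
non-increasing by construction.  Empty clusters are repaired by reseeding
with the point farthest from its current centroid.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import AnnotationValue, CompoundSet
from .similarity import Fingerprint, path_fingerprint, tanimoto

__all__ = [
    "PickResult",
    "ClusterResult",
    "tanimoto_distance",
    "maxmin_select",
    "kmeans",
    "cluster_set",
]


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - Tanimoto(a, b)."""
    return 1.0 - tanimoto(a, b)


@dataclass
class PickResult:
    picked_indices: list[int]
    min_distances: list[float]  # distance of each pick to the previous picks
    seed_index: int
    rng_seed: Optional[int]


def maxmin_select(fps: list[Fingerprint], k: int,
                  seed_index: Optional[int] = None,
                  rng_seed: Optional[int] = None) -> PickResult:
    """Pick ``k`` diverse fingerprints by the MaxMin rule.

    The first pick is ``seed_index`` when given, otherwise drawn from
    ``rng_seed`` (index 0 when neither is given, so default runs are
    reproducible).  Deterministic for a fixed seed.
    """
    n = len(fps)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if seed_index is None:
        seed_index = random.Random(rng_seed).randrange(n) if rng_seed is not None else 0
    if not 0 <= seed_index < n:
        raise ValueError("seed_index out of range")

    picked = [seed_index]
    min_dist = [tanimoto_distance(fps[i], fps[seed_index]) for i in range(n)]
    min_dist[seed_index] = -1.0  # never re-picked
    radii = [float("inf")]  # the seed has no previous picks
    while len(picked) < k:
        best_idx = max(range(n), key=lambda i: (min_dist[i], -i))
        radii.append(min_dist[best_idx])
        picked.append(best_idx)
        for i in range(n):
            if min_dist[i] >= 0:
                d = tanimoto_distance(fps[i], fps[best_idx])
                if d < min_dist[i]:
                    min_dist[i] = d
        min_dist[best_idx] = -1.0
    return PickResult(picked_indices=picked, min_distances=radii,
                      seed_index=seed_index, rng_seed=rng_seed)


@dataclass
class ClusterResult:
    assignments: list[int]
    centroids: np.ndarray  # (k, nbits) real-valued
    objective: float
    iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)


def _continuous_tanimoto(x: np.ndarray, c: np.ndarray) -> float:
    num = float(x @ c)
    den = float(x @ x) + float(c @ c) - num
    return num / den if den > 0 else 1.0  # both all-zero: identical


def _objective(vecs: np.ndarray, assign: list[int], centroids: np.ndarray) -> float:
    return sum(1.0 - _continuous_tanimoto(vecs[i], centroids[assign[i]])
               for i in range(len(assign)))


def kmeans(fps: list[Fingerprint], k: int, init_indices: list[int],
           max_iter: int = 100, tol: float = 1e-6,
           rng_seed: Optional[int] = None) -> ClusterResult:
    """k-means over continuous Tanimoto similarity to real-valued centroids."""
    n = len(fps)
    if k > n:
        raise ValueError(f"k={k} exceeds number of fingerprints ({n})")
    if len(init_indices) != k:
        raise ValueError("init_indices must have length k")
    vecs = np.stack([fp.to_vector() for fp in fps])
    centroids = vecs[list(init_indices)].copy()

    def assign_points(cents: np.ndarray) -> list[int]:
        out = []
        for i in range(n):
            sims = [_continuous_tanimoto(vecs[i], cents[j]) for j in range(k)]
            out.append(int(np.argmax(sims)))  # ties -> lowest cluster index
        return out

    assignments = assign_points(centroids)
    objective = _objective(vecs, assignments, centroids)
    history = [objective]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_cent = centroids.copy()
        for j in range(k):
            members = [i for i in range(n) if assignments[i] == j]
            if members:
                new_cent[j] = vecs[members].mean(axis=0)
            else:
                # reseed with the point farthest from its own centroid
                far = min(range(n),
                          key=lambda i: _continuous_tanimoto(
                              vecs[i], new_cent[assignments[i]]))
                new_cent[j] = vecs[far]
        new_assign = assign_points(new_cent)
        new_obj = _objective(vecs, new_assign, new_cent)
        if new_obj > objective:  # roll back: objective history stays monotone
            converged = True
            break
        improved = objective - new_obj
        centroids, assignments, objective = new_cent, new_assign, new_obj
        history.append(objective)
        if improved < tol:
            converged = True
            break
    # guarantee non-empty clusters on output
    for j in range(k):
        if j not in assignments:
            far = min(range(n),
                      key=lambda i: _continuous_tanimoto(vecs[i],
                                                         centroids[assignments[i]]))
            assignments[far] = j
            centroids[j] = vecs[far]
    objective = _objective(vecs, assignments, centroids)
    return ClusterResult(assignments=assignments, centroids=centroids,
                         objective=objective, iterations=iterations,
                         converged=converged, objective_history=history)


def cluster_set(cset: CompoundSet, k: int, rng_seed: Optional[int] = None,
                nbits: int = 1024, depth: int = 7,
                max_iter: int = 100, tol: float = 1e-6
                ) -> tuple[CompoundSet, ClusterResult]:
    """Full pipeline: fingerprints -> MaxMin picks -> k-means with the picks
    as initial centroids.  Records are annotated with their cluster index
    and whether they were a MaxMin pick (cluster representative)."""
    if k > len(cset):
        raise ValueError(f"k={k} exceeds set size {len(cset)}")
    fps = [path_fingerprint(rec.mol, nbits=nbits, depth=depth) for rec in cset]
    picks = maxmin_select(fps, k, rng_seed=rng_seed)
    result = kmeans(fps, k, init_indices=picks.picked_indices,
                    max_iter=max_iter, tol=tol, rng_seed=rng_seed)
    for col in ("cluster", "is_representative"):
        if col not in cset.column_names():
            cset.annotation_columns.append((col, "text"))
    for i, rec in enumerate(cset):
        rec.annotations["cluster"] = AnnotationValue("text", str(result.assignments[i]))
        rec.annotations["is_representative"] = AnnotationValue(
            "text", "1" if i in picks.picked_indices else "0")
    return cset, result
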