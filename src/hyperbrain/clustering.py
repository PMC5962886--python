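"""ROI grouping by k-medoids on time-series correlation, for the group lasso.

Regions are grouped by the alternating k-medoids algorithm (assignment to
the nearest medoid, then per-cluster medoid update) on the correlation
dissimilarity 1 - r.  Initial medoids are chosen k-means++-style: the
first uniformly at random, each subsequent one with probability
proportional to its distance from the nearest already-chosen medoid.  The
clustering is restarted (default 10 times) and the minimum-cost partition
kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CohortDataset, ROITimeSeries
from .sparse import GroupStructure

__all__ = ["ROIPartition", "roi_similarity", "kmedoids"]


@dataclass
class ROIPartition:
    """k-medoids grouping of the R regions."""

    assignment: np.ndarray
    medoids: np.ndarray
    cost: float
    k: int
    seed: int

    def to_group_structure(self) -> GroupStructure:
        return GroupStructure(assignment=self.assignment, k=self.k)


def roi_similarity(
    data: CohortDataset | ROITimeSeries, absolute: bool = False
) -> np.ndarray:
    """R x R Pearson-correlation similarity between regions.

    For a cohort, correlations are taken on the time series averaged
    across subjects, producing one similarity matrix (and downstream one
    partition) shared by every subject.  Dissimilarity is 1 - similarity
    (or 1 - |r| with ``absolute=True``).
    """
    if isinstance(data, CohortDataset):
        mat = np.mean([s.data for s in data.subjects], axis=0)
    else:
        mat = data.data
    if np.any(mat.std(axis=0) == 0):
        bad = list(np.flatnonzero(mat.std(axis=0) == 0))
        raise ValueError(f"zero-variance ROI column(s) at indices {bad}")
    sim = np.corrcoef(mat, rowvar=False)
    if absolute:
        sim = np.abs(sim)
    np.fill_diagonal(sim, 1.0)
    return sim


def _seed_medoids(diss: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    r = diss.shape[0]
    first = int(rng.integers(r))
    medoids = [first]
    while len(medoids) < k:
        nearest = diss[:, medoids].min(axis=1)
        nearest[medoids] = 0.0
        total = nearest.sum()
        if total <= 0:  # all remaining points coincide with a medoid
            remaining = [i for i in range(r) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
        else:
            medoids.append(int(rng.choice(r, p=nearest / total)))
    return medoids


def _one_run(diss: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    medoids = np.array(_seed_medoids(diss, k, rng))
    cost = np.inf
    for _ in range(max_iter):
        assign = np.argmin(diss[:, medoids], axis=1)
        assign[medoids] = np.arange(k)  # a medoid always belongs to its own group
        new_medoids = medoids.copy()
        for i in range(k):
            members = np.flatnonzero(assign == i)
            within = diss[np.ix_(members, members)].sum(axis=1)
            new_medoids[i] = members[np.argmin(within)]
        new_cost = float(diss[np.arange(diss.shape[0]), new_medoids[assign]].sum())
        if new_cost >= cost - 1e-12:
            break
        medoids, cost = new_medoids, new_cost
    assign = np.argmin(diss[:, medoids], axis=1)
    assign[medoids] = np.arange(k)
    cost = float(diss[np.arange(diss.shape[0]), medoids[assign]].sum())
    return assign, medoids, cost


def kmedoids(
    similarity: np.ndarray,
    k: int,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> ROIPartition:
    """Partition regions into k groups; best of ``n_restarts`` seeded runs."""
    similarity = np.asarray(similarity, dtype=float)
    r = similarity.shape[0]
    if similarity.shape != (r, r):
        raise ValueError("similarity must be square")
    if not (1 <= k <= r):
        raise ValueError(f"k must lie in [1, {r}], got {k}")
    diss = 1.0 - similarity
    np.fill_diagonal(diss, 0.0)
    diss = np.maximum(diss, 0.0)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        assign, medoids, cost = _one_run(diss, k, rng, max_iter)
        if best is None or cost < best[2] - 1e-12:
            best = (assign, medoids, cost)
    assign, medoids, cost = best
    return ROIPartition(assignment=assign, medoids=medoids, cost=cost, k=k, seed=seed)
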