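"""Between-group feature statistics and hyper-edge summaries.

Feature selection follows a nonparametric recipe: the two-sample
Kolmogorov–Smirnov statistic per feature, a label-permutation null for its
p-value, and Benjamini–Hochberg FDR control (q = 0.05) across the feature
family.  Relief weights rank the surviving features; average hyper-edges
summarise a group's edges at one (centroid, penalty) cell by occurrence
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from .construction import HyperEdge

__all__ = [
    "FeatureTable",
    "TestResult",
    "ks_statistic",
    "permutation_test",
    "permutation_test_table",
    "bh_fdr",
    "select_features",
    "relief_weights",
    "average_hyperedge",
]


@dataclass
class FeatureTable:
    """Subjects x features matrix with names and group labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match columns")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length must match rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing/non-finite feature values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "group", self.labels)
        if self.subject_ids is not None:
            df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class TestResult:
    """Per-feature KS statistic, permutation p-value and FDR decision."""

    feature_names: list[str]
    ks: np.ndarray
    p_perm: np.ndarray
    rejected: np.ndarray
    q: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "ks_statistic": self.ks,
                "p_perm": self.p_perm,
                "rejected": self.rejected,
            }
        )


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic: sup distance between empirical CDFs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(ks_2samp(a, b).statistic)


def _ks_from_sorted(order_mask: np.ndarray, dup_mask: np.ndarray, n_a: int, n_b: int):
    """KS statistics for rows of a boolean group-membership matrix.

    ``order_mask``: (m, n) booleans, True = group a, columns already in
    sorted-value order; ``dup_mask``: True at positions whose value equals
    the next one (CDF difference not evaluable there).
    """
    cum_a = np.cumsum(order_mask, axis=1) / n_a
    cum_b = np.cumsum(~order_mask, axis=1) / n_b
    diff = np.abs(cum_a - cum_b)
    diff[:, dup_mask] = 0.0
    return diff.max(axis=1)


def permutation_test(
    feature: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the two-sample KS statistic of one feature.

    p = (1 + #{permutations with KS >= observed}) / (1 + n_perm), with
    uniformly drawn label permutations under a fixed seed.
    """
    p = permutation_test_table(
        np.asarray(feature, dtype=float)[:, None], labels, n_perm=n_perm, seed=seed
    )
    return float(p[0])


def permutation_test_table(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Vectorised permutation KS p-values for every column of ``values``.

    The same set of label permutations is used for all features.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"exactly two groups required, found {list(uniq)}")
    is_a = labels == uniq[0]
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    n = len(labels)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perms[i] = is_a[rng.permutation(n)]

    pvals = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        x = values[:, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        dup = np.zeros(n, dtype=bool)
        dup[:-1] = xs[:-1] == xs[1:]
        obs = _ks_from_sorted(is_a[order][None, :], dup, n_a, n_b)[0]
        null = _ks_from_sorted(perms[:, order], dup, n_a, n_b)
        pvals[j] = (1.0 + np.sum(null >= obs - 1e-12)) / (1.0 + n_perm)
    return pvals


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejections at FDR level q."""
    pvals = np.asarray(pvals, dtype=float)
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, alpha=q, method="fdr_bh")[0]


def select_features(
    table: FeatureTable, q: float = 0.05, n_perm: int = 10_000, seed: int = 0
) -> TestResult:
    """KS permutation test on every feature, BH-FDR corrected at level q."""
    uniq = np.unique(table.labels)
    if uniq.size != 2:
        raise ValueError("feature selection requires exactly two groups")
    a = table.values[table.labels == uniq[0]]
    b = table.values[table.labels == uniq[1]]
    ks = np.array([ks_statistic(a[:, j], b[:, j]) for j in range(table.values.shape[1])])
    p = permutation_test_table(table.values, table.labels, n_perm=n_perm, seed=seed)
    return TestResult(list(table.feature_names), ks, p, bh_fdr(p, q), q)


def relief_weights(
    table: FeatureTable, n_iterations: int | None = None, seed: int = 0
) -> np.ndarray:
    """Classic binary Relief feature weights.

    For each sampled instance the nearest same-class (hit) and
    other-class (miss) neighbours are found by Euclidean distance, and
    weight_j accumulates (|x_j - miss_j| - |x_j - hit_j|) / n_iterations.
    Defaults to one pass over every instance (sampling without
    replacement).
    """
    x = table.values
    y = table.labels
    n, p = x.shape
    for g in np.unique(y):
        if (y == g).sum() < 2:
            raise ValueError(f"class {g!r} has a single subject: no near-hit exists")
    rng = np.random.default_rng(seed)
    if n_iterations is None or n_iterations >= n:
        picks = rng.permutation(n)
    else:
        picks = rng.choice(n, size=n_iterations, replace=False)
    w = np.zeros(p)
    for i in picks:
        d = np.linalg.norm(x - x[i], axis=1)
        d[i] = np.inf
        same = y == y[i]
        hit = np.where(same, d, np.inf).argmin()
        miss = np.where(~same, d, np.inf).argmin()
        w += np.abs(x[i] - x[miss]) - np.abs(x[i] - x[hit])
    return w / len(picks)


def average_hyperedge(
    subject_edges: list[HyperEdge] | list[frozenset[int]],
) -> frozenset[int]:
    """Group-average hyper-edge at one (centroid, penalty) cell.

    Pools one hyper-edge per subject, sets d = ceil(mean edge degree) and
    returns the d most frequently occurring regions (ties broken by lower
    region index).
    """
    if not subject_edges:
        raise ValueError("no subjects contributed hyper-edges")
    member_sets = [
        e.members if isinstance(e, HyperEdge) else frozenset(e) for e in subject_edges
    ]
    d = int(np.ceil(np.mean([len(e) for e in member_sets])))
    counts: dict[int, int] = {}
    for e in member_sets:
        for v in e:
            counts[v] = counts.get(v, 0) + 1
    ranked = sorted(counts, key=lambda v: (-counts[v], v))
    return frozenset(ranked[:d])
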