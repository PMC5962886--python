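"""Scikit-learn estimator surface over the hyper-network pipeline.

``HyperNetworkFeatures`` turns a stack of subject time-series matrices
into HCC feature vectors (for the group-lasso branch, the ROI partition is
learned from the training cohort on ``fit``); ``KSPermutationSelector``
keeps the features surviving the permutation-KS / BH-FDR screen; together
with :class:`hyperbrain.classify.NestedSVC` they compose into an ordinary
sklearn :class:`~sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .clustering import kmedoids, roi_similarity
from .construction import DEFAULT_LAMBDA_GRID, HyperNetworkSpec, build_hypernetwork
from .hypergraph import HyperNetwork
from .io import CohortDataset
from .metrics import HCCVector, hcc_features
from .stats import bh_fdr, permutation_test_table

__all__ = ["HyperNetworkFeatures", "KSPermutationSelector", "as_subject_stack"]


def as_subject_stack(X: CohortDataset | np.ndarray | list) -> list[np.ndarray]:
    """Normalise input to a list of per-subject T x R matrices."""
    if isinstance(X, CohortDataset):
        return [s.data for s in X.subjects]
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return [X[i] for i in range(X.shape[0])]
    return [np.asarray(x, dtype=float) for x in X]


class HyperNetworkFeatures(BaseEstimator, TransformerMixin):
    """Transformer: subject time series -> hyper-network HCC features.

    Parameters
    ----------
    method : {'lasso', 'elastic_net', 'group_lasso'}
        Penalty used for the per-region sparse regressions.
    lambda_grid : tuple of float
        Penalty fractions of lambda_max, strictly increasing in (0, 1].
    lambda2 : float
        Ridge weight for the elastic net (ignored otherwise).
    n_groups : int
        k for the k-medoids ROI partition (group lasso only), learned on
        ``fit`` from the training subjects' pooled time series.
    n_restarts : int
        k-medoids restarts.
    standardize : bool
        Z-score each subject's columns before the regressions.
    random_state : int
        Seed for the clustering restarts.
    """

    def __init__(
        self,
        method: str = "lasso",
        lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
        lambda2: float = 0.2,
        n_groups: int = 48,
        n_restarts: int = 10,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.method = method
        self.lambda_grid = lambda_grid
        self.lambda2 = lambda2
        self.n_groups = n_groups
        self.n_restarts = n_restarts
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y=None):
        subjects = as_subject_stack(X)
        if not subjects:
            raise ValueError("need at least one subject")
        self.n_rois_ = subjects[0].shape[1]
        self.partition_ = None
        if self.method == "group_lasso":
            pooled = np.mean([self._prep(s) for s in subjects], axis=0)
            sim = np.corrcoef(pooled, rowvar=False)
            np.fill_diagonal(sim, 1.0)
            self.partition_ = kmedoids(
                sim,
                k=min(self.n_groups, self.n_rois_),
                seed=self.random_state,
                n_restarts=self.n_restarts,
            )
        self.spec_ = HyperNetworkSpec(
            method=self.method,
            lambda_grid=tuple(self.lambda_grid),
            lambda2=self.lambda2,
            groups=self.partition_,
        )
        return self

    def _prep(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        if not self.standardize:
            return data
        sd = data.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance ROI column in subject time series")
        return (data - data.mean(axis=0)) / sd

    def transform_networks(self, X) -> list[HyperNetwork]:
        """Per-subject hyper-networks (R x |grid| hyper-edges each)."""
        check_is_fitted(self, "spec_")
        return [build_hypernetwork(self._prep(s), self.spec_) for s in as_subject_stack(X)]

    def transform_hcc(self, X) -> list[HCCVector]:
        return [hcc_features(net) for net in self.transform_networks(X)]

    def transform(self, X) -> np.ndarray:
        """(n_subjects, 3R) matrix: hcc1 per region, then hcc2, then hcc3."""
        return np.vstack([vec.flatten() for vec in self.transform_hcc(X)])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "n_rois_")
        labels = [f"ROI{j + 1}" for j in range(self.n_rois_)]
        return np.asarray(HCCVector.feature_names(labels), dtype=object)


class KSPermutationSelector(SelectorMixin, BaseEstimator):
    """Feature selector: permutation-KS p-values with BH-FDR control.

    ``fit`` computes, per feature, the two-sample KS statistic between the
    groups in ``y`` and its label-permutation p-value, then keeps the
    features rejected by the Benjamini–Hochberg step-up rule at level
    ``q``.  If nothing survives, the single smallest-p feature is kept so
    a downstream classifier always has input.
    """

    def __init__(self, q: float = 0.05, n_perm: int = 10_000, random_state: int = 0):
        self.q = q
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.pvalues_ = permutation_test_table(
            X, y, n_perm=self.n_perm, seed=self.random_state
        )
        self.rejected_ = bh_fdr(self.pvalues_, self.q)
        mask = self.rejected_.copy()
        if not mask.any():
            mask[np.argmin(self.pvalues_)] = True
        self.support_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
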