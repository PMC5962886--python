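"""Per-region sparse linear regression under lasso, elastic-net and group-lasso penalties.

Each region m is modelled as a sparse linear combination of all other
regions: with x_m the centroid region's time series and A_m the full
time-series matrix with column m zeroed, the solvers minimise

    lasso:        (1/2)||x_m - A_m a||^2 + lam * ||a||_1
    elastic net:  (1/2)||x_m - A_m a||^2 + lam1 * ||a||_1 + lam2 * ||a||_2^2
    group lasso:  (1/2)||x_m - A_m a||^2 + beta * sum_i ||a_{G_i}||_2

Penalty levels are expressed as fractions of the method's lambda_max, the
smallest level at which the all-zero solution is optimal, so grids in
(0, 1] are comparable across regions and subjects.  Lasso and elastic net
are solved by scikit-learn's coordinate descent; the group lasso by FISTA
with a block soft-threshold proximal step and an explicit block-KKT
convergence check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lasso_path, ElasticNet

__all__ = [
    "RegressionProblem",
    "SparseSolution",
    "GroupStructure",
    "compute_lambda_max",
    "solve_lasso",
    "solve_elastic_net",
    "solve_group_lasso",
    "solve_path",
    "kkt_residual",
]

SUPPORT_TOL = 1e-8
KKT_TOL = 1e-6
MAX_ITER = 10_000


@dataclass
class RegressionProblem:
    """Sparse regression instance for one centroid region."""

    response: np.ndarray  # x_m, length T
    design: np.ndarray  # A_m, T x R with column centroid_index all zero
    centroid_index: int

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.design = np.asarray(self.design, dtype=float)
        t, r = self.design.shape
        if t < 2:
            raise ValueError("need at least 2 timepoints")
        if self.response.shape[0] != t:
            raise ValueError("response length must match design rows")
        if not (0 <= self.centroid_index < r):
            raise ValueError("centroid_index out of range")
        if np.any(self.design[:, self.centroid_index] != 0):
            raise ValueError("design column at centroid_index must be all zeros")
        if not (np.all(np.isfinite(self.response)) and np.all(np.isfinite(self.design))):
            raise ValueError("non-finite values in regression problem")

    @classmethod
    def from_timeseries(cls, data: np.ndarray, centroid_index: int) -> "RegressionProblem":
        """Build x_m / A_m from a T x R matrix by zeroing column m."""
        data = np.asarray(data, dtype=float)
        design = data.copy()
        design[:, centroid_index] = 0.0
        return cls(data[:, centroid_index].copy(), design, centroid_index)


@dataclass
class GroupStructure:
    """Non-overlapping assignment of the R regions into k groups."""

    assignment: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be a vector")
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.assignment.min() < 0 or self.assignment.max() >= self.k:
            raise ValueError("group ids must lie in [0, k)")

    def members(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == i)


@dataclass
class SparseSolution:
    """Fitted coefficient vector alpha_m with its support and penalty metadata."""

    coefficients: np.ndarray
    centroid_index: int
    method: str
    lambda_fraction: float
    lambda_max: float
    objective_value: float
    lambda2: float = 0.0
    groups: GroupStructure | None = None
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.support = np.flatnonzero(np.abs(self.coefficients) > SUPPORT_TOL)


def compute_lambda_max(
    problem: RegressionProblem, method: str, groups: GroupStructure | None = None
) -> float:
    """Smallest penalty level at which the all-zero coefficient vector is optimal.

    lasso / elastic net: max_j |a_j' x|; group lasso (unweighted groups):
    max_i ||A_{G_i}' x||_2.  Returns 0 when the response is orthogonal to
    every column.
    """
    z = problem.design.T @ problem.response
    if method in ("lasso", "elastic_net"):
        return float(np.max(np.abs(z))) if z.size else 0.0
    if method == "group_lasso":
        if groups is None:
            raise ValueError("group_lasso requires a GroupStructure")
        norms = [np.linalg.norm(z[groups.members(i)]) for i in range(groups.k)]
        return float(max(norms)) if norms else 0.0
    raise ValueError(f"unknown method {method!r}")


def _objective(
    problem: RegressionProblem,
    coef: np.ndarray,
    method: str,
    lam1: float,
    lam2: float = 0.0,
    groups: GroupStructure | None = None,
) -> float:
    resid = problem.response - problem.design @ coef
    obj = 0.5 * float(resid @ resid)
    if method == "lasso":
        return obj + lam1 * float(np.abs(coef).sum())
    if method == "elastic_net":
        return obj + lam1 * float(np.abs(coef).sum()) + lam2 * float(coef @ coef)
    if method == "group_lasso":
        return obj + lam1 * sum(
            float(np.linalg.norm(coef[groups.members(i)])) for i in range(groups.k)
        )
    raise ValueError(method)


def kkt_residual(
    problem: RegressionProblem,
    coef: np.ndarray,
    method: str,
    lam1: float,
    lam2: float = 0.0,
    groups: GroupStructure | None = None,
) -> float:
    """Sup-norm violation of the first-order optimality conditions."""
    g = problem.design.T @ (problem.design @ coef - problem.response)
    if method == "elastic_net":
        g = g + 2.0 * lam2 * coef
    if method in ("lasso", "elastic_net"):
        active = np.abs(coef) > SUPPORT_TOL
        res = np.where(
            active, np.abs(g + lam1 * np.sign(coef)), np.maximum(np.abs(g) - lam1, 0.0)
        )
        res[problem.centroid_index] = 0.0
        return float(res.max()) if res.size else 0.0
    if method == "group_lasso":
        worst = 0.0
        for i in range(groups.k):
            idx = groups.members(i)
            cg, gg = coef[idx], g[idx]
            nrm = np.linalg.norm(cg)
            if nrm > SUPPORT_TOL:
                worst = max(worst, float(np.linalg.norm(gg + lam1 * cg / nrm)))
            else:
                worst = max(worst, max(float(np.linalg.norm(gg)) - lam1, 0.0))
        return worst
    raise ValueError(method)


def _zero_solution(problem, method, frac, lam_max, lam2=0.0, groups=None) -> SparseSolution:
    coef = np.zeros(problem.design.shape[1])
    return SparseSolution(
        coef,
        problem.centroid_index,
        method,
        frac,
        lam_max,
        _objective(problem, coef, method, frac * lam_max, lam2, groups),
        lambda2=lam2,
        groups=groups,
    )


def solve_lasso(problem: RegressionProblem, lambda_fraction: float) -> SparseSolution:
    """l1-penalised solve at lam = lambda_fraction * lambda_max."""
    return solve_path(problem, "lasso", [lambda_fraction])[0]


def solve_elastic_net(
    problem: RegressionProblem, lambda1_fraction: float, lambda2: float
) -> SparseSolution:
    """l1+l2-penalised solve; lam1 is a fraction of the *lasso* lambda_max."""
    return solve_path(problem, "elastic_net", [lambda1_fraction], lambda2=lambda2)[0]


def solve_group_lasso(
    problem: RegressionProblem, beta_fraction: float, groups: GroupStructure
) -> SparseSolution:
    """l2,1-penalised solve at beta = beta_fraction * group lambda_max."""
    return solve_path(problem, "group_lasso", [beta_fraction], groups=groups)[0]


def solve_path(
    problem: RegressionProblem,
    method: str,
    fractions: list[float],
    lambda2: float = 0.0,
    groups: GroupStructure | None = None,
    tol: float = KKT_TOL,
) -> list[SparseSolution]:
    """Solve at every penalty fraction in ``fractions`` (order preserved).

    Fractions are solved jointly (path / warm starts) where the backend
    allows, which is what makes whole-network construction cheap.
    """
    fractions = [float(f) for f in fractions]
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"penalty fraction must lie in (0, 1], got {f}")
    if method == "elastic_net" and lambda2 < 0:
        raise ValueError("lambda2 must be nonnegative")

    lam_max = compute_lambda_max(
        problem, "lasso" if method == "elastic_net" else method, groups
    )
    if lam_max == 0.0:  # response orthogonal to all columns: any penalty zeroes out
        return [
            _zero_solution(problem, method, f, lam_max, lambda2, groups) for f in fractions
        ]

    order = np.argsort(fractions)[::-1]  # descending penalty for warm starts
    coefs: dict[int, np.ndarray] = {}
    t = problem.design.shape[0]

    if method == "lasso" or (method == "elastic_net" and lambda2 == 0.0):
        alphas = [fractions[i] * lam_max / t for i in order]
        _, path_coefs, _ = lasso_path(
            problem.design, problem.response, alphas=alphas, tol=min(1e-10, tol), max_iter=MAX_ITER
        )
        for pos, i in enumerate(order):
            coefs[i] = path_coefs[:, pos].copy()
    elif method == "elastic_net":
        model = None
        for i in order:
            lam1 = fractions[i] * lam_max
            alpha = (lam1 + 2.0 * lambda2) / t
            l1_ratio = lam1 / (lam1 + 2.0 * lambda2)
            if model is None:
                model = ElasticNet(
                    alpha=alpha,
                    l1_ratio=l1_ratio,
                    fit_intercept=False,
                    tol=min(1e-10, tol),
                    max_iter=MAX_ITER,
                    warm_start=True,
                )
            else:
                model.set_params(alpha=alpha, l1_ratio=l1_ratio)
            model.fit(problem.design, problem.response)
            coefs[i] = model.coef_.copy()
    elif method == "group_lasso":
        if groups is None:
            raise ValueError("group_lasso requires a GroupStructure")
        coef = np.zeros(problem.design.shape[1])
        for i in order:
            coef = _fista_group_lasso(problem, fractions[i] * lam_max, groups, coef, tol)
            coefs[i] = coef.copy()
    else:
        raise ValueError(f"unknown method {method!r}")

    out = []
    for i, f in enumerate(fractions):
        coef = coefs[i]
        coef[np.abs(coef) <= SUPPORT_TOL] = 0.0
        coef[problem.centroid_index] = 0.0
        lam1 = f * lam_max
        out.append(
            SparseSolution(
                coef,
                problem.centroid_index,
                method,
                f,
                lam_max,
                _objective(problem, coef, method, lam1, lambda2, groups),
                lambda2=lambda2,
                groups=groups,
            )
        )
    return out


def _fista_group_lasso(
    problem: RegressionProblem,
    beta: float,
    groups: GroupStructure,
    init: np.ndarray,
    kkt_tol: float = KKT_TOL,
) -> np.ndarray:
    """FISTA with block soft-threshold prox; stops on block-KKT residual."""
    a, x = problem.design, problem.response
    gram = a.T @ a
    atx = a.T @ x
    lip = float(np.linalg.eigvalsh(gram)[-1])
    if lip == 0.0:
        return np.zeros_like(init)
    group_idx = [groups.members(i) for i in range(groups.k)]
    tol = kkt_tol * max(beta, compute_lambda_max(problem, "group_lasso", groups))

    coef = init.copy()
    y = coef.copy()
    t_k = 1.0
    for it in range(MAX_ITER):
        grad = gram @ y - atx
        z = y - grad / lip
        new = z.copy()
        thr = beta / lip
        for idx in group_idx:
            nrm = np.linalg.norm(z[idx])
            new[idx] = 0.0 if nrm <= thr else (1.0 - thr / nrm) * z[idx]
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
        y = new + ((t_k - 1.0) / t_next) * (new - coef)
        coef, t_k = new, t_next
        if it % 10 == 0 and kkt_residual(problem, coef, "group_lasso", beta, 0.0, groups) <= tol:
            break
    return coef
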