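"""Sparse solvers: closed forms, exact oracles, KKT certificates, invariances."""

import numpy as np
import pytest

from hyperbrain.sparse import (
    GroupStructure,
    RegressionProblem,
    compute_lambda_max,
    kkt_residual,
    solve_elastic_net,
    solve_group_lasso,
    solve_lasso,
    solve_path,
)

from conftest import group_lasso_duality_gap, sign_enumeration_oracle


def _random_problem(rng, t=30, r=8, centroid=0):
    a = rng.standard_normal((t, r))
    a[:, centroid] = 0.0
    x = rng.standard_normal(t)
    return RegressionProblem(x, a, centroid)


def _orthonormal_problem(atx=2.0):
    # centroid column 0 zeroed; column 1 is a unit vector with a'x = atx
    a = np.zeros((4, 2))
    a[0, 1] = 1.0
    x = np.array([atx, 0.0, 0.0, 0.0])
    return RegressionProblem(x, a, 0)


class TestLambdaMax:
    def test_single_column_analytic(self):
        prob = _orthonormal_problem(atx=2.0)
        assert compute_lambda_max(prob, "lasso") == pytest.approx(2.0)

    def test_orthogonal_response_gives_zero(self):
        a = np.zeros((4, 3))
        a[0, 1] = 1.0
        a[1, 2] = 1.0
        x = np.array([0.0, 0.0, 1.0, 0.0])
        prob = RegressionProblem(x, a, 0)
        assert compute_lambda_max(prob, "lasso") == 0.0
        sol = solve_lasso(prob, 0.5)
        assert sol.support.size == 0

    def test_group_norm_closed_form(self):
        # one group holding all columns, z = A'x = (3, 4) -> lambda_max = 5
        a = np.zeros((6, 3))
        a[0, 1] = 1.0
        a[1, 2] = 1.0
        x = np.zeros(6)
        x[0], x[1] = 3.0, 4.0
        prob = RegressionProblem(x, a, 0)
        groups = GroupStructure(np.zeros(3, dtype=int), 1)
        assert compute_lambda_max(prob, "group_lasso", groups) == pytest.approx(5.0)


class TestClosedForms:
    def test_lasso_soft_threshold(self):
        sol = solve_lasso(_orthonormal_problem(2.0), 0.5)
        np.testing.assert_allclose(sol.coefficients, [0.0, 1.0], atol=1e-8)

    def test_lasso_at_lambda_max_is_empty(self):
        sol = solve_lasso(_orthonormal_problem(2.0), 1.0)
        assert sol.support.size == 0

    def test_elastic_net_shrunk_soft_threshold(self):
        # lam1 = 1 (fraction 0.5 of lam_max 2), lam2 = 0.5 -> (2-1)/(1+1) = 0.5
        sol = solve_elastic_net(_orthonormal_problem(2.0), 0.5, 0.5)
        np.testing.assert_allclose(sol.coefficients, [0.0, 0.5], atol=1e-8)

    def test_elastic_net_lambda2_zero_reduces_to_lasso(self):
        rng = np.random.default_rng(0)
        prob = _random_problem(rng)
        enet = solve_elastic_net(prob, 0.4, 0.0)
        lasso = solve_lasso(prob, 0.4)
        np.testing.assert_allclose(enet.coefficients, lasso.coefficients, atol=1e-8)

    def test_group_block_soft_threshold(self):
        a = np.zeros((6, 3))
        a[0, 1] = 1.0
        a[1, 2] = 1.0
        x = np.zeros(6)
        x[0], x[1] = 3.0, 4.0
        prob = RegressionProblem(x, a, 0)
        groups = GroupStructure(np.zeros(3, dtype=int), 1)
        sol = solve_group_lasso(prob, 2.0 / 5.0, groups)  # beta = 2
        np.testing.assert_allclose(sol.coefficients, [0.0, 1.8, 2.4], atol=1e-8)

    def test_group_at_beta_max_is_empty(self):
        rng = np.random.default_rng(1)
        prob = _random_problem(rng)
        groups = GroupStructure(np.array([0, 0, 1, 1, 2, 2, 3, 3]), 4)
        sol = solve_group_lasso(prob, 1.0, groups)
        assert sol.support.size == 0

    def test_group_orthogonal_to_response_is_zeroed(self):
        a = np.zeros((6, 4))
        a[0, 1] = 1.0
        a[2, 2] = 1.0  # group 1: column 2 orthogonal to x
        a[3, 3] = 1.0  # group 1: column 3 orthogonal to x
        x = np.zeros(6)
        x[0] = 5.0
        prob = RegressionProblem(x, a, 0)
        groups = GroupStructure(np.array([0, 0, 1, 1]), 2)
        sol = solve_group_lasso(prob, 0.2, groups)
        assert np.all(sol.coefficients[[2, 3]] == 0)
        assert sol.coefficients[1] > 0


class TestOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_lasso_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        prob = _random_problem(rng)
        for frac in (0.2, 0.5, 0.8):
            sol = solve_lasso(prob, frac)
            lam = frac * sol.lambda_max
            obj_star, _ = sign_enumeration_oracle(
                prob.response, prob.design, lam, skip=(0,)
            )
            assert sol.objective_value == pytest.approx(obj_star, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_elastic_net_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        prob = _random_problem(rng)
        lam2 = 0.3
        for frac in (0.2, 0.6):
            sol = solve_elastic_net(prob, frac, lam2)
            lam1 = frac * sol.lambda_max
            obj_star, _ = sign_enumeration_oracle(
                prob.response, prob.design, lam1, lam2=lam2, skip=(0,)
            )
            assert sol.objective_value == pytest.approx(obj_star, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_group_lasso_duality_gap_certificate(self, seed):
        rng = np.random.default_rng(200 + seed)
        prob = _random_problem(rng)
        groups = GroupStructure(np.array([0, 0, 1, 1, 2, 2, 3, 3]), 4)
        idx = [groups.members(i) for i in range(4)]
        for frac in (0.3, 0.7):
            sol = solve_path(prob, "group_lasso", [frac], groups=groups, tol=1e-12)[0]
            beta = frac * compute_lambda_max(prob, "group_lasso", groups)
            gap = group_lasso_duality_gap(
                prob.response, prob.design, sol.coefficients, beta, idx
            )
            assert -1e-10 < gap < 1e-8  # tiny negative = rounding at exact optimum


class TestProperties:
    def test_kkt_residual_within_tolerance(self):
        rng = np.random.default_rng(3)
        prob = _random_problem(rng, t=60, r=8)
        groups = GroupStructure(np.array([0, 0, 1, 1, 2, 2, 3, 3]), 4)
        for method, kwargs in (
            ("lasso", {}),
            ("elastic_net", {"lambda2": 0.2}),
            ("group_lasso", {"groups": groups}),
        ):
            for sol in solve_path(prob, method, [0.1, 0.5, 0.9], **kwargs):
                lam_method = "lasso" if method == "elastic_net" else method
                lam_max = compute_lambda_max(prob, lam_method, kwargs.get("groups"))
                res = kkt_residual(
                    prob,
                    sol.coefficients,
                    method,
                    sol.lambda_fraction * lam_max,
                    kwargs.get("lambda2", 0.0),
                    kwargs.get("groups"),
                )
                assert res <= 1e-6 * lam_max

    def test_support_monotone_in_penalty(self):
        rng = np.random.default_rng(8)
        grid = np.round(np.arange(0.1, 1.0, 0.1), 10)
        for _ in range(3):
            prob = _random_problem(rng, t=40, r=6)
            sizes = [sol.support.size for sol in solve_path(prob, "lasso", list(grid))]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_grouping_effect_duplicate_columns(self):
        rng = np.random.default_rng(4)
        t = 50
        base = rng.standard_normal((t, 5))
        base[:, 0] = 0.0
        base[:, 2] = base[:, 1]  # exact duplicate pair
        x = base[:, 1] + 0.1 * rng.standard_normal(t)
        prob = RegressionProblem(x, base, 0)
        enet = solve_elastic_net(prob, 0.3, 0.2)
        assert enet.coefficients[1] == pytest.approx(enet.coefficients[2], abs=1e-6)
        assert enet.coefficients[1] > 0
        lasso = solve_lasso(prob, 0.3)
        assert np.sum(np.abs(lasso.coefficients[[1, 2]]) > 1e-8) <= 1

    def test_group_lasso_same_group_duplicates_equal(self):
        rng = np.random.default_rng(6)
        t = 50
        a = rng.standard_normal((t, 4))
        a[:, 0] = 0.0
        a[:, 3] = a[:, 2]
        x = a[:, 2] + 0.1 * rng.standard_normal(t)
        prob = RegressionProblem(x, a, 0)
        groups = GroupStructure(np.array([0, 1, 2, 2]), 3)
        sol = solve_path(prob, "group_lasso", [0.3], groups=groups, tol=1e-10)[0]
        assert sol.coefficients[2] == pytest.approx(sol.coefficients[3], abs=1e-6)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        prob = _random_problem(rng, t=40, r=6, centroid=2)
        sol = solve_lasso(prob, 0.3)
        perm = np.array([3, 0, 2, 5, 1, 4])  # keeps centroid column at index 2
        prob_p = RegressionProblem(prob.response, prob.design[:, perm], 2)
        sol_p = solve_lasso(prob_p, 0.3)
        np.testing.assert_allclose(sol_p.coefficients, sol.coefficients[perm], atol=1e-8)

    def test_centroid_coefficient_always_zero(self):
        rng = np.random.default_rng(9)
        prob = _random_problem(rng, centroid=4)
        for method in ("lasso", "elastic_net"):
            sol = solve_path(prob, method, [0.2], lambda2=0.1)[0]
            assert sol.coefficients[4] == 0.0

    def test_invalid_fraction_rejected(self):
        prob = _orthonormal_problem()
        with pytest.raises(ValueError, match="fraction"):
            solve_lasso(prob, 0.0)
        with pytest.raises(ValueError, match="fraction"):
            solve_lasso(prob, 1.5)
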