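"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hyperbrain.hypergraph import HyperNetwork
from hyperbrain.simulate import SimulationConfig, simulate_cohort

# ---------------------------------------------------------------------------
# Worked 7-node, 4-edge hyper-graph (0-based):
#   e1={v1,v2}, e2={v3,v4,v6}, e3={v5,v6}, e4={v5,v6,v7}
TOY_EDGES = [{0, 1}, {2, 3, 5}, {4, 5}, {4, 5, 6}]


@pytest.fixture(scope="session")
def toy_net() -> HyperNetwork:
    return HyperNetwork(n_nodes=7, edges=[frozenset(e) for e in TOY_EDGES])


@pytest.fixture(scope="session")
def small_cohort():
    """10-ROI, 2-block cohort with a strong injected group difference."""
    cfg = SimulationConfig(
        n_control=6,
        n_patient=6,
        n_rois=10,
        n_timepoints=80,
        block_partition=[[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]],
        within_block_corr=0.5,
        affected_rois=[0, 1],
        effect_size=1.0,
        seed=7,
    )
    return simulate_cohort(cfg)


def random_hypergraph(rng: np.random.Generator, max_nodes=12, max_edges=20) -> HyperNetwork:
    n = int(rng.integers(3, max_nodes + 1))
    m = int(rng.integers(1, max_edges + 1))
    edges = []
    for _ in range(m):
        size = int(rng.integers(1, n + 1))
        edges.append(frozenset(map(int, rng.choice(n, size=size, replace=False))))
    return HyperNetwork(n_nodes=n, edges=edges)


# ---------------------------------------------------------------------------
# Brute-force hyper-graph oracles (set enumeration straight from definitions)


def brute_neighbors(edges, v):
    return {u for e in edges if v in e for u in e} - {v}


def brute_hcc1(edges, v):
    nv = brute_neighbors(edges, v)
    if len(nv) < 2:
        return 0.0
    cnt = sum(
        1
        for u, t in itertools.combinations(sorted(nv), 2)
        if any(u in e and t in e and v not in e for e in edges)
    )
    return 2.0 * cnt / (len(nv) * (len(nv) - 1))


def brute_hcc2(edges, v):
    nv = brute_neighbors(edges, v)
    if len(nv) < 2:
        return 0.0
    cnt = sum(
        1
        for u, t in itertools.combinations(sorted(nv), 2)
        if any(u in e and t in e and v in e for e in edges)
    )
    return 2.0 * cnt / (len(nv) * (len(nv) - 1))


def brute_hcc3(edges, v):
    nv = brute_neighbors(edges, v)
    sv = [e for e in edges if v in e]
    if len(sv) <= 1 or not nv:
        return 0.0
    total = sum(len(e) - 1 for e in sv)
    return (2.0 * total - len(nv)) / (len(nv) * (len(sv) - 1))


# ---------------------------------------------------------------------------
# Exact sparse-regression oracles


def sign_enumeration_oracle(x, a, lam1, lam2=0.0, skip=()):
    """Global optimum of (1/2)||x - a c||^2 + lam1 ||c||_1 + lam2 ||c||_2^2
    by enumerating every support subset and sign pattern (exact for small R).

    Columns in ``skip`` (e.g. the zeroed centroid) are forced inactive.
    Returns (objective, coefficients).
    """
    r = a.shape[1]
    candidates = [j for j in range(r) if j not in skip and np.any(a[:, j])]
    best_obj = 0.5 * float(x @ x)
    best_coef = np.zeros(r)
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            sub = a[:, subset]
            gram = sub.T @ sub + 2.0 * lam2 * np.eye(size)
            atx = sub.T @ x
            for signs in itertools.product([-1.0, 1.0], repeat=size):
                s = np.array(signs)
                try:
                    c = np.linalg.solve(gram, atx - lam1 * s)
                except np.linalg.LinAlgError:
                    continue
                if np.any(np.sign(c) != s):
                    continue
                coef = np.zeros(r)
                coef[list(subset)] = c
                resid = x - a @ coef
                obj = (
                    0.5 * float(resid @ resid)
                    + lam1 * float(np.abs(coef).sum())
                    + lam2 * float(coef @ coef)
                )
                if obj < best_obj:
                    best_obj, best_coef = obj, coef
    return best_obj, best_coef


def group_lasso_duality_gap(x, a, coef, beta, group_index):
    """Certified suboptimality bound for the group-lasso objective.

    Scales the residual into the dual-feasible region and returns
    primal(coef) - dual(u) >= primal(coef) - primal(optimum).
    """
    resid = x - a @ coef
    primal = 0.5 * float(resid @ resid) + beta * sum(
        float(np.linalg.norm(coef[idx])) for idx in group_index
    )
    norms = [np.linalg.norm(a[:, idx].T @ resid) for idx in group_index]
    biggest = max(norms) if norms else 0.0
    scale = 1.0 if biggest <= beta else beta / biggest
    u = scale * resid
    dual = float(u @ x) - 0.5 * float(u @ u)
    return primal - dual
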