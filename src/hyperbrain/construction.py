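"""Hyper-network construction from per-region sparse regressions.

For every centroid region m and every penalty level in the grid, a
hyper-edge is formed from m plus the regions with nonzero coefficient in
the sparse solution.  With R regions and a g-level grid this yields a
fixed R x (R*g) incidence matrix per subject (90 x 810 at the standard
90-region parcellation with the 9-level 0.1..0.9 grid); singleton edges
(empty support) and duplicate edges across levels are retained so the
shape is invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ROIPartition
from .hypergraph import HyperNetwork
from .io import ROITimeSeries
from .sparse import RegressionProblem, solve_path

__all__ = [
    "HyperEdge",
    "HyperNetworkSpec",
    "DEFAULT_LAMBDA_GRID",
    "build_hyperedges_for_roi",
    "build_hypernetwork",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass
class HyperEdge:
    """One hyper-edge: the centroid region plus its selected interactors."""

    centroid: int
    members: frozenset[int]
    method: str
    lambda_fraction: float
    lambda2: float = 0.0
    singleton: bool = False  # empty support at this penalty level

    def __post_init__(self) -> None:
        self.members = frozenset(self.members) | {self.centroid}
        self.singleton = len(self.members) == 1


@dataclass
class HyperNetworkSpec:
    """Construction settings: penalty method and regularization grid."""

    method: str = "lasso"
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    lambda2: float = 0.2
    groups: ROIPartition | None = None

    def __post_init__(self) -> None:
        if self.method not in ("lasso", "elastic_net", "group_lasso"):
            raise ValueError(f"unknown method {self.method!r}")
        grid = tuple(float(v) for v in self.lambda_grid)
        if not grid:
            raise ValueError("lambda_grid must be nonempty")
        if any(not (0.0 < v <= 1.0) for v in grid):
            raise ValueError("grid values must lie in (0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("lambda_grid must be strictly increasing")
        self.lambda_grid = grid
        if self.method == "group_lasso" and self.groups is None:
            raise ValueError("group_lasso requires an ROIPartition")

    def prefix(self, n_levels: int) -> "HyperNetworkSpec":
        """Ascending-prefix sub-grid {l1}, {l1, l2}, ... used in multi-level sweeps."""
        return HyperNetworkSpec(
            self.method, self.lambda_grid[:n_levels], self.lambda2, self.groups
        )


def build_hyperedges_for_roi(
    ts: ROITimeSeries | np.ndarray, m: int, spec: HyperNetworkSpec
) -> list[HyperEdge]:
    """One hyper-edge per grid level for centroid region m."""
    data = ts.data if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)
    problem = RegressionProblem.from_timeseries(data, m)
    groups = spec.groups.to_group_structure() if spec.groups is not None else None
    sols = solve_path(
        problem, spec.method, list(spec.lambda_grid), lambda2=spec.lambda2, groups=groups
    )
    return [
        HyperEdge(
            centroid=m,
            members=frozenset(int(j) for j in sol.support),
            method=spec.method,
            lambda_fraction=frac,
            lambda2=spec.lambda2 if spec.method == "elastic_net" else 0.0,
        )
        for frac, sol in zip(spec.lambda_grid, sols)
    ]


def build_hypernetwork(
    ts: ROITimeSeries | np.ndarray, spec: HyperNetworkSpec
) -> HyperNetwork:
    """Full subject hyper-network: R x |grid| edges, centroid-major order."""
    data = ts.data if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)
    r = data.shape[1]
    all_edges: list[HyperEdge] = []
    for m in range(r):
        all_edges.extend(build_hyperedges_for_roi(data, m, spec))
    net = HyperNetwork(
        n_nodes=r,
        edges=[e.members for e in all_edges],
        metadata={
            "method": spec.method,
            "lambda_grid": spec.lambda_grid,
            "lambda2": spec.lambda2,
            "hyperedges": all_edges,
        },
    )
    return net
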