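"""Hyper-graph algebra: incidence matrix, node/edge degrees, adjacency.

A hyper-graph H = (V, E) generalises a graph by letting each hyper-edge
connect any number of nodes.  It is represented by the |V| x |E| binary
incidence matrix H with H(v, e) = 1 iff v is a member of e; node degree
d(v) is the row sum, edge degree delta(e) the column sum, and the
adjacency matrix A = H H' - D_v counts, off the diagonal, the hyper-edges
containing both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["HyperNetwork", "incidence_matrix", "node_degree", "edge_degree", "adjacency"]


def incidence_matrix(edges: Iterable[Iterable[int]], n_nodes: int) -> np.ndarray:
    """|V| x |E| binary matrix with H(v, e) = 1 iff node v belongs to edge e."""
    edges = [frozenset(e) for e in edges]
    h = np.zeros((n_nodes, len(edges)), dtype=int)
    for j, e in enumerate(edges):
        for v in e:
            if not (0 <= v < n_nodes):
                raise IndexError(f"edge {j} contains node {v} outside [0, {n_nodes})")
            h[v, j] = 1
    return h


@dataclass
class HyperNetwork:
    """Hyper-graph with cached incidence matrix and degree vectors."""

    n_nodes: int
    edges: list[frozenset[int]]
    metadata: dict = field(default_factory=dict)
    incidence: np.ndarray = field(init=False)
    node_degrees: np.ndarray = field(init=False)
    edge_degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.edges = [frozenset(e) for e in self.edges]
        self.incidence = incidence_matrix(self.edges, self.n_nodes)
        self.node_degrees = self.incidence.sum(axis=1)
        self.edge_degrees = self.incidence.sum(axis=0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def star(self, v: int) -> list[int]:
        """Indices of the hyper-edges containing node v (the set S(v))."""
        return list(np.flatnonzero(self.incidence[v]))

    def neighbors(self, v: int) -> set[int]:
        """Nodes sharing at least one hyper-edge with v, excluding v (N(v))."""
        out: set[int] = set()
        for j in self.star(v):
            out |= self.edges[j]
        out.discard(v)
        return out


def node_degree(net: HyperNetwork, v: int) -> int:
    """Number of hyper-edges containing v."""
    return int(net.node_degrees[v])


def edge_degree(net: HyperNetwork, e: int) -> int:
    """Number of nodes in hyper-edge e."""
    return int(net.edge_degrees[e])


def adjacency(net: HyperNetwork) -> np.ndarray:
    """A = H H' - D_v: off-diagonal counts of shared hyper-edges, zero diagonal."""
    h = net.incidence
    return h @ h.T - np.diag(net.node_degrees)
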