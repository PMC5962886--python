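"""Hyper-network clustering coefficients (HCC1, HCC2, HCC3).

Three node-level clustering coefficients summarise the local structure of
a hyper-network.  With N(v) the neighbours of v (nodes sharing an edge
with v, v excluded) and S(v) the edges containing v:

  HCC1(v): fraction of neighbour pairs co-occurring in an edge *without* v
           -- connections not facilitated by v.
  HCC2(v): fraction of neighbour pairs co-occurring in an edge *with* v
           -- connections facilitated by v.
  HCC3(v) = (2 * sum_{e in S(v)} (|e| - 1) - |N(v)|) / (|N(v)| * (|S(v)| - 1))
           -- overlap among the edges of v.

Pair sums run over unordered pairs with the leading factor 2 and the
ordered-pair denominator |N(v)|(|N(v)|-1), so HCC1 and HCC2 lie in [0, 1].
Nodes with a vanishing denominator (|N(v)| <= 1, or |S(v)| <= 1 for HCC3)
receive 0 and a degeneracy flag; averages include flagged zeros by
default, with a strict mode that drops them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypergraph import HyperNetwork

__all__ = [
    "HCCVector",
    "AverageHCC",
    "neighbors",
    "star",
    "hcc1",
    "hcc2",
    "hcc3",
    "hcc_features",
    "average_hcc",
]


def neighbors(net: HyperNetwork, v: int) -> set[int]:
    """N(v): nodes co-occurring with v in at least one hyper-edge, v excluded."""
    return net.neighbors(v)


def star(net: HyperNetwork, v: int) -> list[int]:
    """S(v): indices of the hyper-edges containing v."""
    return net.star(v)


def _pair_indicators(net: HyperNetwork, v: int) -> tuple[int, int, int]:
    """(#pairs connected without v, #pairs connected with v, |N(v)|)."""
    nv = sorted(net.neighbors(v))
    n = len(nv)
    if n < 2:
        return 0, 0, n
    pos = {u: i for i, u in enumerate(nv)}
    without = np.zeros((n, n), dtype=bool)
    with_v = np.zeros((n, n), dtype=bool)
    for j, e in enumerate(net.edges):
        inter = [pos[u] for u in e if u in pos]
        if len(inter) < 2:
            continue
        idx = np.array(inter)
        target = with_v if v in e else without
        target[np.ix_(idx, idx)] = True
    iu = np.triu_indices(n, 1)
    return int(without[iu].sum()), int(with_v[iu].sum()), n


def hcc1(net: HyperNetwork, v: int) -> float:
    """Neighbour connections not facilitated by v; 0 if |N(v)| <= 1."""
    cnt, _, n = _pair_indicators(net, v)
    return 0.0 if n < 2 else 2.0 * cnt / (n * (n - 1))


def hcc2(net: HyperNetwork, v: int) -> float:
    """Neighbour connections facilitated by v; 0 if |N(v)| <= 1."""
    _, cnt, n = _pair_indicators(net, v)
    return 0.0 if n < 2 else 2.0 * cnt / (n * (n - 1))


def hcc3(net: HyperNetwork, v: int) -> float:
    """Overlap among the hyper-edges of v; 0 if |S(v)| <= 1 or |N(v)| = 0."""
    s = net.star(v)
    n = len(net.neighbors(v))
    if len(s) <= 1 or n == 0:
        return 0.0
    total = sum(len(net.edges[j]) - 1 for j in s)
    return (2.0 * total - n) / (n * (len(s) - 1))


@dataclass
class HCCVector:
    """All three coefficients for every node, with degeneracy flags."""

    hcc1: np.ndarray
    hcc2: np.ndarray
    hcc3: np.ndarray
    degenerate_pairs: np.ndarray  # |N(v)| <= 1: hcc1/hcc2 denominators vanish
    degenerate_star: np.ndarray  # |S(v)| <= 1 or |N(v)| = 0: hcc3 denominator vanishes

    def flatten(self) -> np.ndarray:
        """Length 3R feature vector (hcc1 for all nodes, then hcc2, then hcc3)."""
        return np.concatenate([self.hcc1, self.hcc2, self.hcc3])

    @staticmethod
    def feature_names(roi_labels: list[str]) -> list[str]:
        return [f"{m}_{lab}" for m in ("hcc1", "hcc2", "hcc3") for lab in roi_labels]


@dataclass
class AverageHCC:
    """Per-subject means of the three coefficients over all R nodes."""

    mean_hcc1: float
    mean_hcc2: float
    mean_hcc3: float


def hcc_features(net: HyperNetwork) -> HCCVector:
    """All three metrics for all nodes (3R values; 270 at R=90)."""
    r = net.n_nodes
    v1 = np.empty(r)
    v2 = np.empty(r)
    v3 = np.empty(r)
    dpair = np.zeros(r, dtype=bool)
    dstar = np.zeros(r, dtype=bool)
    for v in range(r):
        cnt_without, cnt_with, n = _pair_indicators(net, v)
        if n < 2:
            dpair[v] = True
            v1[v] = v2[v] = 0.0
        else:
            denom = n * (n - 1)
            v1[v] = 2.0 * cnt_without / denom
            v2[v] = 2.0 * cnt_with / denom
        s = int(net.node_degrees[v])
        if s <= 1 or n == 0:
            dstar[v] = True
            v3[v] = 0.0
        else:
            total = sum(net.edge_degrees[j] - 1 for j in net.star(v))
            v3[v] = (2.0 * total - n) / (n * (s - 1))
    return HCCVector(v1, v2, v3, dpair, dstar)


def average_hcc(vec: HCCVector, drop_degenerate: bool = False) -> AverageHCC:
    """Arithmetic mean of each metric over nodes.

    Flagged (degenerate) nodes contribute their 0 by default; with
    ``drop_degenerate=True`` they are excluded from the mean instead.
    """
    if vec.hcc1.size == 0:
        raise ValueError("empty network has no average clustering coefficient")

    def _mean(vals: np.ndarray, flags: np.ndarray) -> float:
        if drop_degenerate:
            keep = ~flags
            if not keep.any():
                return 0.0
            return float(vals[keep].mean())
        return float(vals.mean())

    return AverageHCC(
        _mean(vec.hcc1, vec.degenerate_pairs),
        _mean(vec.hcc2, vec.degenerate_pairs),
        _mean(vec.hcc3, vec.degenerate_star),
    )
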