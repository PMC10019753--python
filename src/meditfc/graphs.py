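"""Weighted graph metrics on connectivity matrices.

Two graph-theoretic features summarize each connectivity graph:

* the Onnela weighted clustering coefficient, a per-node measure of
  triangle density weighted by edge strengths (local segregation),

      C_j = 2 / (k_j (k_j - 1)) * sum_{k<l} (w_jk * w_jl * w_kl)^(1/3),

  with k_j the number of nonzero-weight neighbors of j; nodes with
  fewer than two neighbors get C_j = 0;

* the characteristic path length, the average shortest-path distance
  over node pairs with edge distance d = 1/w (stronger connectivity =
  shorter distance), computed with Dijkstra's algorithm from every
  source. It is an inverse proxy for global efficiency: a shorter
  characteristic path means better-integrated connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix


@dataclass
class WeightedGraph:
    """Undirected weighted graph: symmetric weights in [0, 1], zero diagonal."""

    nodes: list[str]
    weights: np.ndarray
    hemispheres: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != len(self.nodes):
            raise ValueError("weights must be square and match the node list")
        if np.any(w < 0):
            raise ValueError("negative edge weights are not allowed")
        if np.any(w > 1 + 1e-12):
            raise ValueError("edge weights must lie in [0, 1]")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w


@dataclass
class GraphMetrics:
    """Clustering and path-length summary of one weighted graph."""

    per_node_cc: np.ndarray
    mean_cc: float
    char_path_length: float
    finite_pair_fraction: float


def to_weighted_graph(cm: ConnectivityMatrix, *, threshold_q: float = 1.0) -> WeightedGraph:
    """Connectivity matrix -> weighted graph.

    Correlation entries enter as |r| (a strong negative association is
    still coupling, and weights must stay in [0, 1]); PLV entries enter
    as-is. ``threshold_q`` keeps only the strongest fraction q of edges
    (proportional threshold); the default q = 1 keeps all edges.
    """
    if not (0.0 <= threshold_q <= 1.0):
        raise ValueError("threshold_q must lie in [0, 1]")
    w = np.abs(np.asarray(cm.matrix, dtype=float).copy())
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    if threshold_q < 1.0:
        iu = np.triu_indices_from(w, k=1)
        vals = w[iu]
        present = vals > 0
        n_keep = int(round(threshold_q * int(present.sum())))
        if n_keep < int(present.sum()):
            order = np.argsort(vals)[::-1]  # strongest first
            drop = order[n_keep:]
            w[iu[0][drop], iu[1][drop]] = 0.0
            w = np.triu(w, k=1)
            w = w + w.T
    labels = [lab for lab, _ in cm.channel_index]
    return WeightedGraph(
        nodes=labels, weights=w, hemispheres=[h for _, h in cm.channel_index]
    )


def clustering_coefficient(g: WeightedGraph) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node, and its mean over nodes of
    degree >= 2 (nodes with fewer neighbors contribute C_j = 0 and are
    excluded from the mean)."""
    w = g.weights
    k = (w > 0).sum(axis=1)
    w3 = np.cbrt(w)
    # diagonal of (W^(1/3))^3 counts each (ordered) neighbor pair once,
    # which is exactly the 2 * sum over unordered pairs in the formula
    tri = np.diagonal(w3 @ w3 @ w3).copy()
    cc = np.zeros(len(k))
    eligible = k >= 2
    cc[eligible] = tri[eligible] / (k[eligible] * (k[eligible] - 1))
    mean = float(cc[eligible].mean()) if eligible.any() else 0.0
    return cc, mean


def shortest_paths(g: WeightedGraph, *, distance: str = "inverse") -> np.ndarray:
    """All-pairs shortest-path distances via Dijkstra from every source.

    Edge distance is d = 1/w (default) or d = 1 - w; zero-weight pairs
    carry no edge; unreachable pairs get +inf.
    """
    w = g.weights
    if distance == "inverse":
        dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    elif distance == "one_minus":
        # w = 1 edges get a tiny positive distance so they stay edges
        dist = np.where(w > 0, np.maximum(1.0 - w, 1e-12), 0.0)
    else:
        raise ValueError(f"unknown distance convention {distance!r}")
    # scipy's dense csgraph convention: zero entries mean "no edge"
    return dijkstra(dist, directed=False)


def characteristic_path_length(distances: np.ndarray) -> tuple[float, float]:
    """Mean over finite off-diagonal pairwise distances, plus the finite
    fraction. Returns (+inf, 0.0) for a graph with no finite pair."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return float("inf"), 0.0
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    frac = float(finite.mean())
    if not finite.any():
        return float("inf"), 0.0
    return float(vals[finite].mean()), frac


def compute_graph_metrics(g: WeightedGraph) -> GraphMetrics:
    cc, mean_cc = clustering_coefficient(g)
    spl, frac = characteristic_path_length(shortest_paths(g))
    return GraphMetrics(
        per_node_cc=cc, mean_cc=mean_cc, char_path_length=spl, finite_pair_fraction=frac
    )


def edge_list(g: WeightedGraph) -> list[tuple[str, str, float]]:
    """Weighted edge list (source, target, weight) for external inspection."""
    iu = np.triu_indices_from(g.weights, k=1)
    return [
        (g.nodes[i], g.nodes[j], float(g.weights[i, j]))
        for i, j in zip(*iu)
        if g.weights[i, j] > 0
    ]
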