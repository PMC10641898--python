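"""State-specific functional networks and normalized closeness centrality.

Correlated pairs of one behavioral state form an undirected graph whose
edge weights are the pairs' Pearson correlations.  Edge length is
``d(i, j) = log(1 / w)``, so strong correlations are short.  Closeness of
node ``i`` is ``c(i) = (A_i / (N - 1))^2 / C_i`` where ``A_i`` counts the
nodes reachable from ``i`` and ``C_i`` sums the weighted shortest-path
distances to them; the squared reachable fraction rewards belonging to a
large connected component.  The network-level value is the node mean
times ``N`` (equivalently the sum of c), which keeps the measure
comparable across networks of different sizes.  All recorded cells enter
the graph — isolated cells contribute c = 0 and still count in ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .connectivity import CORRELATED, PairResult

W_CLIP = 1.0 - 1e-9  # r = 1 between distinct cells would give zero distance


@dataclass
class CentralityResult:
    nodes: list
    c: np.ndarray  # closeness per node
    A: np.ndarray  # reachable-node counts
    C: np.ndarray  # summed shortest-path distances (0 where A = 0)

    @property
    def network_mean_normalized(self) -> float:
        return float(self.c.mean() * self.c.size)


def build_graph(
    pairs: list[PairResult],
    nodes: list | None = None,
    state: str | None = None,
) -> nx.Graph:
    """Simple undirected graph with one edge per correlated pair.

    ``nodes`` lists every recorded cell (isolated ones are kept); when
    omitted, nodes are inferred from the pair list.  Edge weight is the
    pair's r, clipped just below 1.
    """
    g = nx.Graph()
    if state is not None:
        g.graph["state"] = state
    if nodes is not None:
        g.add_nodes_from(nodes)
    for pr in pairs:
        if nodes is None:
            g.add_nodes_from([pr.i, pr.j])
        if pr.klass == CORRELATED:
            w = min(float(pr.r), W_CLIP)
            if w <= 0:
                raise ValueError("correlated pairs must have positive r")
            g.add_edge(pr.i, pr.j, weight=w)
    return g


def closeness(g: nx.Graph, log_base: str = "e") -> CentralityResult:
    """Normalized closeness centrality of every node.

    Edge lengths are ``log(1/w)`` (natural log by default, base 10 via
    ``log_base="10"``); shortest paths by Dijkstra.  Disconnected nodes
    get c = 0.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    lengths = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
    w = lengths.data
    if np.any(w <= 0) or np.any(w > 1):
        raise ValueError("edge weights must lie in (0, 1]")
    lengths.data = np.log(1.0 / np.minimum(w, W_CLIP))
    if log_base == "10":
        lengths.data /= np.log(10.0)
    # explicit zeros would be dropped by csgraph: clip guarantees d > 0
    dist = dijkstra(lengths, directed=False)
    np.fill_diagonal(dist, np.inf)  # exclude self
    reach = np.isfinite(dist)
    A = reach.sum(axis=1)
    C = np.where(reach, dist, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(A > 0, (A / (n - 1)) ** 2 / np.where(C > 0, C, 1.0), 0.0)
    return CentralityResult(nodes=nodes, c=c, A=A.astype(int), C=C)


def network_mean(result: CentralityResult) -> float:
    """Node-mean closeness times node count (= sum of per-node closeness)."""
    return result.network_mean_normalized


def centrality_difference(rest: nx.Graph | CentralityResult,
                          run: nx.Graph | CentralityResult,
                          log_base: str = "e") -> float:
    """Rest-minus-run difference of the normalized network closeness."""
    if isinstance(rest, nx.Graph):
        rest = closeness(rest, log_base=log_base)
    if isinstance(run, nx.Graph):
        run = closeness(run, log_base=log_base)
    return network_mean(rest) - network_mean(run)
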