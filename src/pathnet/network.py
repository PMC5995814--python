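"""Pathway network construction: threshold scan, pruning, structure stats.

The all-pairs similarity scores form a near-complete weighted graph.  To
expose structure, edges below a cut-off are dropped.  The cut-off is
chosen by scanning an even grid of candidate thresholds and maximizing
(fraction of nodes keeping at least one edge) minus (fraction of edges
kept) -- i.e. linking the most nodes with the fewest edges.  Reported
statistics: average (Watts-Strogatz) clustering coefficient against
degree-preserving randomizations, and a discrete power-law fit of the
degree distribution (Clauset-Shalizi-Newman MLE + KS, via igraph's plfit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import igraph
import networkx as nx
import numpy as np
import pandas as pd

Edge = tuple[str, str, float]


@dataclass
class PathwayNetwork:
    """Pruned pathway graph; all nodes kept, isolated ones flagged."""

    graph: nx.Graph
    threshold: float
    provenance: dict | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def isolated(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.degree() if d == 0)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def as_edge_list(weights) -> list[Edge]:
    """Normalize a square DataFrame or an (u, v, w) iterable to an edge list.

    Self-pairs are dropped; endpoints are canonically ordered u < v;
    zero-weight pairs are treated as non-edges.
    """
    if isinstance(weights, pd.DataFrame):
        edges = []
        ids = list(weights.index)
        for i, u in enumerate(ids):
            for v in ids[i + 1 :]:
                w = float(weights.loc[u, v])
                if w > 0:
                    edges.append((u, v, w))
        return edges
    out = []
    for u, v, w in weights:
        if u == v:
            continue
        if w > 0:
            a, b = (u, v) if u < v else (v, u)
            out.append((a, b, float(w)))
    return sorted(set(out))


def _node_universe(weights, edges: list[Edge]) -> list[str]:
    if isinstance(weights, pd.DataFrame):
        return sorted(weights.index)
    return sorted({u for u, _, _ in edges} | {v for _, v, _ in edges})


def threshold_scan(weights, n_thresholds: int = 50) -> tuple[float, pd.DataFrame]:
    """Pick the pruning threshold maximizing nodeFrac - edgeFrac.

    Candidate thresholds are the even grid k/(n+1), k = 1..n, strictly
    inside (0, 1).  nodeFrac(t) is the fraction of nodes with at least one
    incident edge of weight >= t; edgeFrac(t) the fraction of edges of
    weight >= t.  Ties break toward the larger threshold among candidates
    that still retain nodes (an equally scoring empty network is never
    preferred over a non-empty one).  Returns the chosen threshold and the
    full scan table.
    """
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    edges = as_edge_list(weights)
    if not edges:
        raise ValueError("no positive similarity weights to scan")
    nodes = _node_universe(weights, edges)
    n_nodes, n_edges = len(nodes), len(edges)
    rows = []
    best = None
    for k in range(1, n_thresholds + 1):
        theta = k / (n_thresholds + 1)
        kept = [(u, v) for u, v, w in edges if w >= theta]
        touched = {u for u, _ in kept} | {v for _, v in kept}
        node_frac = len(touched) / n_nodes
        edge_frac = len(kept) / n_edges
        score = node_frac - edge_frac
        rows.append(
            {"threshold": theta, "node_frac": node_frac, "edge_frac": edge_frac, "score": score}
        )
        key = (score, node_frac > 0, theta)  # ties -> non-empty, then larger theta
        if best is None or key >= best:
            best = key
    return best[2], pd.DataFrame(rows)


def prune(weights, threshold: float, provenance: dict | None = None) -> PathwayNetwork:
    """Keep edges with weight >= threshold; all nodes stay in the graph."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    edges = as_edge_list(weights)
    nodes = _node_universe(weights, edges)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from((u, v, w) for u, v, w in edges if w >= threshold)
    return PathwayNetwork(graph=g, threshold=threshold, provenance=provenance)


def clustering_coefficient(net: PathwayNetwork) -> float:
    """Watts-Strogatz average local clustering; degree<2 nodes contribute 0."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    return float(nx.average_clustering(net.graph, count_zeros=True))


def degree_preserving_randomize(
    net: PathwayNetwork, n_swaps: int | None = None, seed: int = 0
) -> PathwayNetwork:
    """Double-edge-swap randomization preserving the exact degree sequence."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(net.graph.edges)
    m = g.number_of_edges()
    if m < 2 or g.number_of_nodes() < 4:
        warnings.warn("network admits no degree-preserving swap; returning a copy")
        return PathwayNetwork(graph=g, threshold=net.threshold, provenance=net.provenance)
    if n_swaps is None:
        n_swaps = 10 * m
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXError as exc:
        warnings.warn(f"randomization stopped early: {exc}")
    return PathwayNetwork(graph=g, threshold=net.threshold, provenance=net.provenance)


@dataclass
class PowerLawFit:
    alpha: float
    xmin: float
    ks_statistic: float
    p: float


def power_law_test(degrees: Iterable[int], seed: int = 0) -> PowerLawFit:
    """Discrete power-law fit (MLE alpha, KS-optimal xmin, bootstrap GoF p).

    A p below 0.05 rejects the power-law hypothesis for the degree
    distribution.  Degrees of 0 are excluded; a degenerate (all-equal)
    sequence has no fittable tail and raises.  The goodness-of-fit p is
    simulation-based; *seed* pins igraph's RNG so results reproduce.
    """
    degs: Sequence[int] = [int(d) for d in degrees if d >= 1]
    if len(degs) < 10:
        raise ValueError("need at least 10 nodes with degree >= 1")
    if len(set(degs)) == 1:
        raise ValueError("degenerate degree sequence: all degrees equal")
    import random as _random

    state = _random.getstate()
    _random.seed(seed)  # igraph's default RNG is the stdlib random module
    try:
        fit = igraph.power_law_fit(degs)
    finally:
        _random.setstate(state)
    return PowerLawFit(
        alpha=float(fit.alpha),
        xmin=float(fit.xmin),
        ks_statistic=float(fit.D),
        p=float(fit.p),
    )


def write_edge_list(net: PathwayNetwork, path) -> None:
    rows = [
        {"u": u, "v": v, "weight": d.get("weight", 1.0)}
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["u", "v", "weight"]).to_csv(path, sep="\t", index=False)


def write_graphml(net: PathwayNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
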