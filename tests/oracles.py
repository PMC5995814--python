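"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (exhaustive enumeration,
direct summation, plain BFS) and deliberately avoids the code paths under
test.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import comb


def bfs_ancestors(parent_edges: dict[str, set[str]], term: str) -> set[str]:
    """Plain BFS transitive closure over child->parent edges."""
    seen: set[str] = set()
    frontier = list(parent_edges.get(term, ()))
    while frontier:
        t = frontier.pop()
        if t in seen:
            continue
        seen.add(t)
        frontier.extend(parent_edges.get(t, ()))
    return seen


def all_paths_svalue(
    weighted_parents: dict[str, list[tuple[str, float]]], anchor: str
) -> dict[str, float]:
    """S-values by exhaustive path enumeration: max product of edge weights
    over all child->parent paths from the anchor to each ancestor."""
    best: dict[str, float] = {anchor: 1.0}

    def walk(node: str, product: float) -> None:
        for parent, w in weighted_parents.get(node, ()):
            p = product * w
            if p > best.get(parent, 0.0):
                best[parent] = p
            walk(parent, p)

    walk(anchor, 1.0)
    return best


def wang_sim_brute(
    weighted_parents: dict[str, list[tuple[str, float]]], a: str, b: str
) -> float:
    sa = all_paths_svalue(weighted_parents, a)
    sb = all_paths_svalue(weighted_parents, b)
    common = set(sa) & set(sb)
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def hypergeom_tail_brute(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def bh_adjust_brute(pvalues: list[float]) -> list[float]:
    """Step-up BH computed directly from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def min_set_cover_brute(candidates: dict[str, frozenset[str]], universe: frozenset[str]):
    """Smallest covering sub-collection by exhaustive search (tiny instances)."""
    ids = sorted(candidates)
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            if frozenset().union(*(candidates[c] for c in combo)) >= universe:
                return combo
    return None


def threshold_scan_brute(edges, nodes, n_thresholds=50):
    """Exhaustive evaluation of the scan objective over the candidate grid."""
    best = None
    for k in range(1, n_thresholds + 1):
        theta = k / (n_thresholds + 1)
        kept = [(u, v) for u, v, w in edges if w >= theta]
        touched = {x for e in kept for x in e}
        score = len(touched) / len(nodes) - len(kept) / len(edges)
        if best is None or score >= best[0]:
            best = (score, theta)
    return best[1]


def clustering_brute(adjacency: dict[str, set[str]]) -> float:
    """Average local clustering by explicit triangle / triple counting."""
    vals = []
    for node, nbrs in adjacency.items():
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(
            1
            for u, v in itertools.combinations(sorted(nbrs), 2)
            if v in adjacency[u]
        )
        vals.append(2 * links / (k * (k - 1)))
    return sum(vals) / len(vals)


def bfs_distances(adjacency: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def pairwise_distance_multiset(adjacency: dict[str, set[str]], nodes: list[str]) -> Counter:
    out: Counter = Counter()
    for i, u in enumerate(nodes):
        dist = bfs_distances(adjacency, u)
        for v in nodes[i + 1 :]:
            if v in dist:
                out[dist[v]] += 1
    return out
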