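"""GO semantic similarity: Wang and Resnik term measures, set aggregation.

Term level
----------
The Wang measure scores two terms by the weighted ancestor contributions
they share.  For an anchor term A, every term t in A's ancestor-closed
subgraph gets an S-value: S_A(A) = 1, and S_A(t) is the best product of
per-edge decay weights along any child->parent path from A to t, with
``is_a`` edges weighted 0.8 and ``part_of`` edges 0.6 (the canonical Wang
defaults; ``is_a`` must outweigh ``part_of``).  The similarity of a and b
is the shared S-mass divided by the total S-mass:

    sim(a, b) = sum_{t in T_a ∩ T_b} (S_a(t) + S_b(t)) / (SV(a) + SV(b))

The Resnik measure scores two terms by the information content of their
most informative common ancestor (MICA), IC(t) = -log p(t) with p(t) the
fraction of annotated genes carrying t after ancestor propagation.  Scores
are divided by the corpus maximum IC so both measures live on the same
[0, 1] edge-weight scale.

Set level
---------
Two aggregations lift a term measure to pathway profiles: the pairwise
average (mean over the full cross product) and the best-match average
(symmetric mean of per-term best matches).  The BMA dominates the pairwise
average and assigns 1 to identical profiles, which is why it is the
default for network edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.stats import ks_2samp

from pathnet.annotations import AnnotationTable
from pathnet.ontology import IS_A, PART_OF, OntologyDAG

TermSim = Callable[[str, str], float]


@dataclass(frozen=True)
class WangWeights:
    is_a: float = 0.8
    part_of: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.part_of < 1 and 0 < self.is_a < 1):
            raise ValueError("Wang weights must lie in (0, 1)")
        if self.is_a <= self.part_of:
            raise ValueError("is_a weight must exceed part_of weight")

    def of(self, relation: str) -> float:
        if relation == IS_A:
            return self.is_a
        if relation == PART_OF:
            return self.part_of
        raise KeyError(f"no Wang weight for relation {relation!r}")


@dataclass
class SValueMap:
    """S-values of one anchor term over its ancestor-closed subgraph."""

    term: str
    svalues: dict[str, float]
    sv: float


def wang_svalues(dag: OntologyDAG, term: str, weights: WangWeights = WangWeights()) -> SValueMap:
    """Compute S_A(t) for every t in *term*'s ancestor-closed subgraph.

    S decays multiplicatively along edges; with multiple paths the maximum
    product wins.  Terms are processed in topological (child-before-parent)
    order within the induced subgraph.
    """
    if term not in dag:
        raise KeyError(f"unknown ontology term: {term!r}")
    sub = dag.ancestors(term) | {term}
    g = nx.DiGraph()
    g.add_nodes_from(sub)
    for child in sub:
        for parent, rel in dag.parents(child):
            if parent in sub:
                w = weights.of(rel)
                # parallel is_a/part_of edges collapse to the heavier weight
                if not g.has_edge(child, parent) or g[child][parent]["w"] < w:
                    g.add_edge(child, parent, w=w)
    s: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(g):
        if node == term:
            continue
        s[node] = max(
            s[child] * data["w"] for child, _, data in g.in_edges(node, data=True)
        )
    return SValueMap(term=term, svalues=s, sv=sum(s.values()))


def wang_similarity(
    dag: OntologyDAG, a: str, b: str, weights: WangWeights = WangWeights()
) -> float:
    """Shared-ancestor S-mass fraction; symmetric, in (0, 1]."""
    sa = wang_svalues(dag, a, weights)
    sb = wang_svalues(dag, b, weights)
    common = sa.svalues.keys() & sb.svalues.keys()
    shared = sum(sa.svalues[t] + sb.svalues[t] for t in common)
    return shared / (sa.sv + sb.sv)


@dataclass
class ICMap:
    """Annotation-frequency information content per term."""

    p: dict[str, float]
    ic: dict[str, float]
    max_ic: float

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def build_ic_map(table: AnnotationTable) -> ICMap:
    """IC(t) = -log(annotated-gene fraction of t) from a propagated table.

    Terms carried by no annotated gene are simply absent; after propagation
    the root is carried by every gene, so IC(root) = 0.
    """
    if not table.propagated:
        raise ValueError("IC map requires a propagated annotation table")
    total = len(table)
    if total == 0:
        raise ValueError("annotation table is empty")
    t2g = table.term_to_genes()
    p = {t: len(g) / total for t, g in t2g.items()}
    ic = {t: -math.log(v) for t, v in p.items()}
    informative = [v for v in ic.values() if v > 0]
    max_ic = max(informative) if informative else 0.0
    return ICMap(p=p, ic=ic, max_ic=max_ic)


def resnik_similarity(dag: OntologyDAG, ic: ICMap, a: str, b: str) -> float:
    """Normalized MICA information content, in [0, 1].

    Common-ancestor candidates include a and b themselves, so the
    self-similarity of the corpus-rarest term is 1.  Terms without
    annotated descendants have no defined p and cannot be compared.
    """
    for t in (a, b):
        if t not in dag:
            raise KeyError(f"unknown ontology term: {t!r}")
        if t not in ic:
            raise ValueError(f"term {t!r} has no annotated genes; IC undefined")
    common = (dag.ancestors(a) | {a}) & (dag.ancestors(b) | {b})
    raw = max((ic.ic[t] for t in common if t in ic), default=0.0)
    if ic.max_ic == 0:
        return 0.0
    return min(1.0, max(0.0, raw / ic.max_ic))


def make_termsim(
    dag: OntologyDAG,
    method: str = "wang",
    weights: WangWeights = WangWeights(),
    ic: ICMap | None = None,
) -> TermSim:
    """Build a symmetric, cached term-similarity function."""
    cache: dict[tuple[str, str], float] = {}
    svcache: dict[str, SValueMap] = {}

    if method == "wang":

        def sval(t: str) -> SValueMap:
            if t not in svcache:
                svcache[t] = wang_svalues(dag, t, weights)
            return svcache[t]

        def sim(a: str, b: str) -> float:
            key = (a, b) if a <= b else (b, a)
            hit = cache.get(key)
            if hit is None:
                sa, sb = sval(a), sval(b)
                common = sa.svalues.keys() & sb.svalues.keys()
                hit = sum(sa.svalues[t] + sb.svalues[t] for t in common) / (sa.sv + sb.sv)
                cache[key] = hit
            return hit

        return sim
    if method == "resnik":
        if ic is None:
            raise ValueError("resnik term similarity needs an ICMap")

        def sim(a: str, b: str) -> float:
            key = (a, b) if a <= b else (b, a)
            hit = cache.get(key)
            if hit is None:
                hit = resnik_similarity(dag, ic, a, b)
                cache[key] = hit
            return hit

        return sim
    raise ValueError(f"unknown term-similarity method {method!r}")


def pairwise_average(A: Iterable[str], B: Iterable[str], termsim: TermSim) -> float:
    """Mean term similarity over the full A x B cross product."""
    A, B = sorted(set(A)), sorted(set(B))
    if not A or not B:
        raise ValueError("term sets must be non-empty")
    return sum(termsim(a, b) for a in A for b in B) / (len(A) * len(B))


def best_match_average(A: Iterable[str], B: Iterable[str], termsim: TermSim) -> float:
    """Symmetric mean of per-term best matches between A and B."""
    A, B = sorted(set(A)), sorted(set(B))
    if not A or not B:
        raise ValueError("term sets must be non-empty")
    row = sum(max(termsim(a, b) for b in B) for a in A)
    col = sum(max(termsim(a, b) for a in A) for b in B)
    return (row + col) / (len(A) + len(B))


_AGGREGATIONS = {"pairwise": pairwise_average, "bma": best_match_average}


def set_similarity(A, B, termsim: TermSim, agg: str = "bma") -> float:
    try:
        return _AGGREGATIONS[agg](A, B, termsim)
    except KeyError:
        raise ValueError(f"unknown aggregation {agg!r}") from None


def similarity_matrix(
    term_sets: Mapping[str, Iterable[str]],
    termsim: TermSim,
    agg: str = "bma",
):
    """Symmetric pathway-by-pathway similarity DataFrame (diagonal included)."""
    import pandas as pd

    ids = sorted(term_sets)
    mat = np.zeros((len(ids), len(ids)))
    for i, u in enumerate(ids):
        for j, v in enumerate(ids):
            if j < i:
                continue
            mat[i, j] = mat[j, i] = set_similarity(term_sets[u], term_sets[v], termsim, agg)
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class SeparationResult:
    """Within- vs between-profile similarity distributions for one config."""

    method: str
    level: str  # "term", "pairwise" or "bma"
    within: np.ndarray
    between: np.ndarray
    mean_difference: float = field(init=False)
    ks_statistic: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_difference = float(self.within.mean() - self.between.mean())
        self.ks_statistic = float(ks_2samp(self.within, self.between).statistic)


def separation_report(
    term_sets: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
    ic: ICMap,
    weights: WangWeights = WangWeights(),
) -> dict[str, SeparationResult]:
    """Within- vs between-pathway similarity for all six configurations.

    Configurations are {resnik, wang} x {term, pairwise, bma}.  At the term
    level, "within" pools similarities of distinct term pairs inside one
    profile and "between" pools cross-profile term pairs; at the set level,
    "within" is each profile compared with itself and "between" each
    profile pair.  The separation statistic (difference of means, plus a
    two-sample KS statistic) is what makes the configurations comparable.
    """
    sets = {k: sorted(set(v)) for k, v in term_sets.items() if v}
    ids = sorted(sets)
    if len(ids) < 2:
        raise ValueError("need at least two non-empty profiles")
    out: dict[str, SeparationResult] = {}
    for method in ("resnik", "wang"):
        termsim = make_termsim(dag, method=method, weights=weights, ic=ic)
        term_within = [
            termsim(a, b)
            for pid in ids
            for i, a in enumerate(sets[pid])
            for b in sets[pid][i + 1 :]
        ]
        term_between = [
            termsim(a, b)
            for i, u in enumerate(ids)
            for v in ids[i + 1 :]
            for a in sets[u]
            for b in sets[v]
        ]
        if not term_within:  # all profiles singletons: fall back to self-pairs
            term_within = [termsim(a, a) for pid in ids for a in sets[pid]]
        for level in ("term", "pairwise", "bma"):
            if level == "term":
                within = np.asarray(term_within, dtype=float)
                between = np.asarray(term_between, dtype=float)
            else:
                within = np.asarray(
                    [set_similarity(sets[pid], sets[pid], termsim, level) for pid in ids]
                )
                between = np.asarray(
                    [
                        set_similarity(sets[u], sets[v], termsim, level)
                        for i, u in enumerate(ids)
                        for v in ids[i + 1 :]
                    ]
                )
            out[f"{method}_{level}"] = SeparationResult(
                method=method, level=level, within=within, between=between
            )
    return out
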