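"""Over-representation analysis: one-sided Fisher tests with BH correction.

Used in two places: assigning enriched GO Biological Process terms to each
pathway (with Benjamini-Hochberg adjustment within the pathway's test
family, threshold 0.01), and mapping disease gene sets onto pathway nodes
(raw p < 0.01).  The p-value is the upper hypergeometric tail
P(X >= k) for an overlap of k query genes among K background carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from pathnet.annotations import AnnotationTable
from pathnet.curation import PathwaySet


@dataclass
class EnrichmentResult:
    query_id: str
    term: str
    k: int  # query genes carrying term
    K: int  # background genes carrying term
    n: int  # annotated query size
    N: int  # background size
    p: float
    p_adj: float | None = None


@dataclass
class FunctionalProfile:
    """A pathway's enriched terms, later reduced to a minimal covering set."""

    pathway_id: str
    enriched: list[EnrichmentResult] = field(default_factory=list)
    minimal: list[str] | None = None

    @property
    def enriched_terms(self) -> list[str]:
        return [r.term for r in self.enriched]

    @property
    def terms(self) -> frozenset[str]:
        """Terms used for similarity: minimal profile if built, else all enriched."""
        return frozenset(self.minimal if self.minimal is not None else self.enriched_terms)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    query: Iterable[str],
    term_to_genes: Mapping[str, frozenset[str]],
    background: Iterable[str],
    query_id: str = "query",
) -> list[EnrichmentResult]:
    """One-sided over-representation test for every term hit by the query.

    Term gene sets are intersected with the background before testing;
    terms with no query overlap are omitted.  Results are sorted by
    ascending p (ties by term id).
    """
    query = frozenset(query)
    background = frozenset(background)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= background:
        missing = sorted(query - background)[:3]
        raise ValueError(f"query genes outside background, e.g. {missing}")
    N = len(background)
    n = len(query)
    results: list[EnrichmentResult] = []
    for term in sorted(term_to_genes):
        carriers = term_to_genes[term] & background
        K = len(carriers)
        if K == 0:
            continue
        k = len(query & carriers)
        if k == 0:
            continue
        results.append(
            EnrichmentResult(
                query_id=query_id, term=term, k=k, K=K, n=n, N=N,
                p=hypergeom_tail(k, K, n, N),
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def profile_pathways(
    ps: PathwaySet,
    table: AnnotationTable,
    alpha: float = 0.01,
    background: frozenset[str] | None = None,
) -> list[FunctionalProfile]:
    """Enriched-term profile for every pathway, BH-adjusted within pathway.

    The background universe defaults to the union of annotated genes across
    all pathways in *ps*.  A pathway whose adjusted p-values all exceed
    *alpha* yields an empty profile, flagging it for removal.
    """
    if not table.propagated:
        raise ValueError("annotation table must be propagated before enrichment")
    if background is None:
        background = frozenset().union(
            *(p.genes for p in ps.pathways)
        ) & table.genes if len(ps) else frozenset()
    term_to_genes = table.term_to_genes()
    profiles: list[FunctionalProfile] = []
    for p in ps.pathways:
        query = (p.annotated_genes or p.genes) & background
        if not query:
            profiles.append(FunctionalProfile(pathway_id=p.id))
            continue
        results = fisher_enrichment(query, term_to_genes, background, query_id=p.id)
        adj = bh_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adj = a
        profiles.append(
            FunctionalProfile(
                pathway_id=p.id,
                enriched=[r for r in results if r.p_adj is not None and r.p_adj < alpha],
            )
        )
    return profiles
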