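"""Greedy set-cover reductions.

Two redundancy-reduction steps share set-cover machinery:

* ``minimize_profile`` reduces a pathway's enriched GO terms to a minimal
  set that still covers the pathway's annotated genes, preferring the most
  significant terms; terms describing the same genes at lower significance
  are discarded.
* ``proportional_set_cover`` selects a reduced-redundancy pathway subset:
  greedily by uncovered-gene count, breaking ties toward a target pathway
  size (default: the median candidate size), stopping once a configurable
  fraction of the gene universe is covered.  Stopping just short of 100%
  (the default is 99.95%) lets the algorithm skip enormous catch-all
  pathways whose only contribution is a handful of residual genes.

Both greedy traces are fully deterministic: residual ties break
lexicographically by identifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from pathnet.curation import PathwaySet


def minimize_profile(
    pathway_genes: frozenset[str],
    enriched: Sequence[tuple[str, float, frozenset[str]]],
) -> list[str]:
    """Greedy minimal covering subset of enriched terms.

    *enriched* holds (term, p, carrier genes) with carriers already
    restricted to the pathway's annotated genes.  At each step the term
    with the smallest p among those covering at least one uncovered gene is
    selected (ties: larger uncovered count, then smaller term id); the
    greedy stops when no candidate adds coverage.  A final pass discards
    terms that became redundant -- least significant first -- so the output
    is irredundant: every retained term covers a gene no other retained
    term covers.  Genes covered by no enriched term are simply not part of
    the cover target.
    """
    if not enriched:
        raise ValueError("pathway has no enriched terms; it should have been removed")
    coverable = frozenset().union(*(c for _, _, c in enriched)) & set(pathway_genes)
    uncovered = set(coverable)
    candidates = list(enriched)
    chosen: list[str] = []
    chosen_set: set[str] = set()
    while uncovered:
        best = None
        best_key = None
        for term, p, carriers in candidates:
            if term in chosen_set:
                continue
            gain = len(carriers & uncovered)
            if gain == 0:
                continue
            key = (p, -gain, term)
            if best_key is None or key < best_key:
                best_key = key
                best = (term, carriers)
        if best is None:
            break
        term, carriers = best
        chosen.append(term)
        chosen_set.add(term)
        uncovered -= carriers

    # discard lower-significance terms whose genes the rest already cover
    carrier = {t: c for t, _, c in enriched}
    pval = {t: p for t, p, _ in enriched}
    changed = True
    while changed:
        changed = False
        for term in sorted(chosen, key=lambda t: (-pval[t], t)):
            others = frozenset().union(
                *(carrier[t] for t in chosen if t != term), frozenset()
            )
            if carrier[term] & coverable <= others:
                chosen.remove(term)
                changed = True
                break
    return chosen


@dataclass
class CoverTrace:
    """One greedy selection step of the proportional set cover."""

    iteration: int
    chosen: str
    uncovered_before: int
    uncovered_after: int


def proportional_set_cover(
    ps: PathwaySet,
    target_size: int | None = None,
    coverage_fraction: float = 0.9995,
) -> tuple[PathwaySet, list[CoverTrace]]:
    """Select a reduced-redundancy pathway subset by proportional greedy cover.

    Iteratively picks the pathway covering the most uncovered genes; among
    equals, the pathway whose size is closest to *target_size* wins
    (default target: the median candidate pathway size), with lexicographic
    id as the final tie-break.  Stops once the covered fraction of the gene
    universe reaches *coverage_fraction*; a final pass drops selections
    that became fully redundant (their genes all covered by the rest), in
    reverse selection order, so the output is irredundant without lowering
    the achieved coverage.
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    universe = ps.gene_universe
    if target_size is None:
        sizes = sorted(len(p.genes) for p in ps.pathways)
        target_size = int(pd.Series(sizes).median()) if sizes else 1
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    needed = coverage_fraction * len(universe)
    covered: set[str] = set()
    remaining = {p.id: p for p in ps.pathways}
    order: list[str] = []
    trace: list[CoverTrace] = []
    it = 0
    while len(covered) < needed:
        best_id = None
        best_key = None
        for pid in sorted(remaining):
            p = remaining[pid]
            gain = len(p.genes - covered)
            if gain == 0:
                continue
            key = (-gain, abs(len(p.genes) - target_size), pid)
            if best_key is None or key < best_key:
                best_key = key
                best_id = pid
        if best_id is None:
            raise RuntimeError(
                "coverage fraction unreachable: max achievable "
                f"{len(covered)}/{len(universe)} genes"
            )
        p = remaining.pop(best_id)
        before = len(universe) - len(covered)
        covered |= p.genes
        order.append(best_id)
        it += 1
        trace.append(
            CoverTrace(
                iteration=it,
                chosen=best_id,
                uncovered_before=before,
                uncovered_after=len(universe) - len(covered),
            )
        )
        if len(covered) >= needed:
            break

    by_id = {p.id: p for p in ps.pathways}
    changed = True
    while changed:
        changed = False
        for pid in reversed(order):
            others = frozenset().union(
                frozenset(), *(by_id[q].genes for q in order if q != pid)
            )
            if by_id[pid].genes <= others:
                order.remove(pid)
                changed = True
                break
    kept = [by_id[pid] for pid in order]
    out = PathwaySet(pathways=kept, curation_log=list(ps.curation_log))
    out.logged(
        "proportional_set_cover",
        len(ps) - len(kept),
        f"redundant (not in set cover at fraction {coverage_fraction})",
    )
    return out, trace


@dataclass
class MembershipSummary:
    """Per-gene pathway-membership counts with mean/median summaries."""

    counts: pd.Series
    mean: float
    median: float


def redundancy_histogram(ps: PathwaySet) -> MembershipSummary:
    """How many pathways each gene belongs to (redundancy fingerprint)."""
    counts: dict[str, int] = {}
    for p in ps.pathways:
        for g in p.genes:
            counts[g] = counts.get(g, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    if series.empty:
        return MembershipSummary(counts=series, mean=0.0, median=0.0)
    return MembershipSummary(
        counts=series, mean=float(series.mean()), median=float(series.median())
    )


def trace_frame(trace: list[CoverTrace]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "iteration": t.iteration,
                "chosen": t.chosen,
                "uncovered_before": t.uncovered_before,
                "uncovered_after": t.uncovered_after,
            }
            for t in trace
        ]
    )
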