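"""Gene -> GO term annotations: GAF loading, evidence filtering, propagation.

Annotations inferred from electronic annotation (IEA) are treated as a
separate, lower-confidence evidence class and removed before any analysis;
every other evidence code counts as experimentally validated / curated.
After filtering, each gene's terms are extended with all of their ontology
ancestors (the true-path rule), which is what enrichment and the Resnik
information-content map operate on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, TextIO

from Bio.UniProt import GOA

from pathnet.ontology import OntologyDAG

EXPERIMENTAL = "experimental"
IEA = "IEA"

_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


class GafParseError(ValueError):
    """Raised for malformed GAF input; message names the offending line."""


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> {(term, evidence class)} mapping.

    Genes with no entries are absent from the mapping rather than mapped to
    an empty set.  ``propagated`` records whether ancestor closure has been
    applied.
    """

    entries: Mapping[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    propagated: bool = False

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.entries)

    def terms_for(self, gene: str) -> frozenset[str]:
        return frozenset(t for t, _ in self.entries.get(gene, ()))

    def term_to_genes(self) -> dict[str, frozenset[str]]:
        """Invert the table: term -> genes carrying it."""
        inv: dict[str, set[str]] = {}
        for gene, pairs in self.entries.items():
            for term, _ev in pairs:
                inv.setdefault(term, set()).add(gene)
        return {t: frozenset(g) for t, g in inv.items()}

    def __len__(self) -> int:
        return len(self.entries)


def _read_text(source: str | os.PathLike | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()
    with open(source, "rt", encoding="utf-8") as fh:
        return fh.read()


def load_gaf(source: str | os.PathLike | TextIO, namespace: str = "biological_process") -> AnnotationTable:
    """Load a GAF 2.x file, keeping only the requested aspect.

    Rows with a NOT qualifier are dropped.  Evidence codes map to the
    binary classes used downstream: ``IEA`` stays ``IEA``, everything else
    becomes ``experimental``.
    """
    aspect = _ASPECT.get(namespace, namespace)
    text = _read_text(source)
    # line-level validation first, so errors can carry a line number
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        ncols = len(line.split("\t"))
        if ncols < 15:
            raise GafParseError(
                f"GAF line {lineno} has {ncols} columns, expected >= 15"
            )

    import io

    entries: dict[str, set[tuple[str, str]]] = {}
    for rec in GOA.gafiterator(io.StringIO(text)):
        if rec["Aspect"] != aspect:
            continue
        if "NOT" in rec["Qualifier"]:
            continue
        gene = rec["DB_Object_Symbol"]
        ev = IEA if rec["Evidence"] == IEA else EXPERIMENTAL
        entries.setdefault(gene, set()).add((rec["GO_ID"], ev))
    return AnnotationTable(
        entries={g: frozenset(p) for g, p in entries.items()}, propagated=False
    )


def filter_evidence(table: AnnotationTable) -> AnnotationTable:
    """Drop all IEA entries; genes left with nothing disappear entirely."""
    if table.propagated:
        raise ValueError("filter_evidence must run before propagation")
    kept: dict[str, frozenset[tuple[str, str]]] = {}
    for gene, pairs in table.entries.items():
        surviving = frozenset(p for p in pairs if p[1] != IEA)
        if surviving:
            kept[gene] = surviving
    return AnnotationTable(entries=kept, propagated=False)


def propagate(table: AnnotationTable, dag: OntologyDAG) -> AnnotationTable:
    """Extend each gene's terms with all ontology ancestors.

    Requires an evidence-filtered table (no IEA entries) whose terms all
    exist in *dag*; ``alt_id`` aliases are resolved to canonical terms.
    Idempotent: re-propagating changes nothing.
    """
    out: dict[str, frozenset[tuple[str, str]]] = {}
    for gene, pairs in table.entries.items():
        closure: set[tuple[str, str]] = set()
        for term, ev in pairs:
            if ev == IEA:
                raise ValueError(f"gene {gene!r} still carries IEA entries; filter first")
            canonical = dag.resolve(term)
            if canonical not in dag:
                raise KeyError(f"gene {gene!r} annotated to unknown term {term!r}")
            closure.add((canonical, ev))
            closure.update((a, ev) for a in dag.ancestors(canonical))
        out[gene] = frozenset(closure)
    return AnnotationTable(entries=out, propagated=True)


def restrict_to_genes(table: AnnotationTable, genes) -> AnnotationTable:
    """Subset the table to *genes* (propagation flag preserved)."""
    genes = set(genes)
    return replace(
        table, entries={g: p for g, p in table.entries.items() if g in genes}
    )
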