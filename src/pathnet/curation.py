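"""Pathway curation: GMT loading, deduplication, name filters, coverage filter.

A raw pathway collection (e.g. a ConsensusPathDB-style export) is reduced
to a candidate node set in three stages: exact-duplicate gene sets are
collapsed, pathways whose names indicate disease / drug-metabolism /
addiction states are removed (they depict perturbed rather than healthy
cell states), and pathways with fewer than four annotated genes are
dropped because they are too small for enrichment analysis.  Every stage
appends to a curation log so removals are auditable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from pathnet.annotations import AnnotationTable


class GmtParseError(ValueError):
    """Raised for malformed GMT input; message names the offending line."""


@dataclass
class Pathway:
    id: str
    name: str
    genes: frozenset[str]
    source: str = ""
    # annotated subset, filled by filter_annotation_coverage for enrichment
    annotated_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has an empty gene set")


@dataclass
class PathwaySet:
    pathways: list[Pathway] = field(default_factory=list)
    curation_log: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    def by_id(self, pid: str) -> Pathway:
        for p in self.pathways:
            if p.id == pid:
                return p
        raise KeyError(pid)

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)

    def logged(self, stage: str, removed: int, reason: str) -> None:
        self.curation_log.append((stage, removed, reason))


def _read_text(source: str | os.PathLike | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()
    with open(source, "rt", encoding="utf-8") as fh:
        return fh.read()


def load_gmt(source: str | os.PathLike | TextIO, provenance: str = "") -> PathwaySet:
    """Read a GMT file (id <tab> name <tab> gene...), one pathway per line.

    Duplicate gene symbols within a line are collapsed; a line with fewer
    than three fields is a parse error naming the line.
    """
    pathways: list[Pathway] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"GMT line {lineno} has {len(fields)} fields, expected >= 3"
            )
        pid, name, *genes = fields
        genes = [g for g in genes if g]
        if pid in seen_ids:
            raise GmtParseError(f"GMT line {lineno}: duplicate pathway id {pid!r}")
        seen_ids.add(pid)
        pathways.append(
            Pathway(id=pid, name=name, genes=frozenset(genes), source=provenance)
        )
    return PathwaySet(pathways=pathways)


def write_gmt(ps: PathwaySet, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for p in ps.pathways:
            fh.write("\t".join([p.id, p.name, *sorted(p.genes)]) + "\n")


def deduplicate(ps: PathwaySet) -> PathwaySet:
    """Collapse pathways with identical gene sets, keeping the smallest id."""
    groups: dict[frozenset[str], list[Pathway]] = {}
    for p in ps.pathways:
        groups.setdefault(p.genes, []).append(p)
    kept_ids = {min(g, key=lambda p: p.id).id for g in groups.values()}
    kept = [p for p in ps.pathways if p.id in kept_ids]
    out = PathwaySet(pathways=kept, curation_log=list(ps.curation_log))
    out.logged("deduplicate", len(ps) - len(kept), "identical gene sets")
    return out


# Default name-filter lists. The published analysis used a curated list from
# its supplementary data; these defaults capture the same categories and are
# meant to be overridden with a study-specific list for real data.
DEFAULT_NAME_FILTERS: dict[str, tuple[str, ...]] = {
    "disease": (
        "cancer", "carcinoma", "sarcoma", "melanoma", "leukemia", "lymphoma",
        "tumor", "tumour", "asthma", "infection", "disease", "syndrome",
        "deficiency", "anemia", "diabetes",
    ),
    "drug": (
        "doxorubicin", "statin", "drug metabolism", "metabolism of drug",
        "tamoxifen", "warfarin", "methadone",
    ),
    "addiction": (
        "addiction", "cocaine", "nicotine", "amphetamine", "alcoholism",
        "morphine",
    ),
}


def filter_by_name(
    ps: PathwaySet,
    term_lists: Mapping[str, Sequence[str]] | None = None,
) -> PathwaySet:
    """Remove pathways whose names contain any listed term.

    Matching is case-insensitive substring; per-category removal counts are
    logged separately.  A name matching several categories is counted under
    the first matching category (dict order).
    """
    term_lists = term_lists or DEFAULT_NAME_FILTERS
    if not term_lists or not any(term_lists.values()):
        raise ValueError("term_lists must contain at least one term")
    lowered = {
        cat: [t.lower() for t in terms] for cat, terms in term_lists.items()
    }
    kept: list[Pathway] = []
    removed_by_cat = {cat: 0 for cat in lowered}
    for p in ps.pathways:
        name = p.name.lower()
        hit = None
        for cat, terms in lowered.items():
            if any(t in name for t in terms):
                hit = cat
                break
        if hit is None:
            kept.append(p)
        else:
            removed_by_cat[hit] += 1
    out = PathwaySet(pathways=kept, curation_log=list(ps.curation_log))
    for cat, n in removed_by_cat.items():
        out.logged(f"filter_by_name:{cat}", n, f"name matched {cat} terms")
    return out


def filter_annotation_coverage(
    ps: PathwaySet, table: AnnotationTable, min_annotated: int = 4
) -> PathwaySet:
    """Drop pathways with fewer than *min_annotated* annotated genes.

    Each survivor records its annotated-gene subset, which enrichment uses
    as the query set.
    """
    annotated = table.genes
    kept: list[Pathway] = []
    for p in ps.pathways:
        sub = p.genes & annotated
        if len(sub) >= min_annotated:
            kept.append(
                Pathway(
                    id=p.id,
                    name=p.name,
                    genes=p.genes,
                    source=p.source,
                    annotated_genes=frozenset(sub),
                )
            )
    out = PathwaySet(pathways=kept, curation_log=list(ps.curation_log))
    out.logged(
        "filter_annotation_coverage",
        len(ps) - len(kept),
        f"fewer than {min_annotated} annotated genes",
    )
    return out


def load_name_filters(source: str | os.PathLike | TextIO) -> dict[str, list[str]]:
    """Read name-filter terms from a sectioned text file.

    Sections are ``[category]`` headers; one term per line; ``#`` comments.
    """
    out: dict[str, list[str]] = {}
    current: str | None = None
    for line in _read_text(source).splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            out.setdefault(current, [])
        elif current is None:
            raise ValueError("term list entries must follow a [category] header")
        else:
            out[current].append(line)
    return out
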