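"""Ontology DAG loading and ancestor queries.

The pipeline operates on a Gene Ontology-style sub-ontology (Biological
Process): a rooted DAG whose terms point toward the root through ``is_a``
and ``part_of`` edges.  Only these two relation types are retained, because
the Wang semantic-similarity measure defines decay weights for them alone;
regulates-family and other relationships are dropped at load time.

``alt_id`` aliases are resolved to their canonical term during loading, so
downstream modules only ever see canonical identifiers.
"""

from __future__ import annotations

import io
import logging
import os
import re
from typing import Iterable, Iterator, Mapping, TextIO

import networkx as nx
import obonet

IS_A = "is_a"
PART_OF = "part_of"
RETAINED_RELATIONS = frozenset({IS_A, PART_OF})

_STANZA_RE = re.compile(r"^\[[^\]]+\]\s*$")


class OboParseError(ValueError):
    """Raised for malformed OBO input; message names the offending line."""


class OntologyCycleError(ValueError):
    """Raised when the retained child->parent edges contain a cycle."""


class OntologyDAG:
    """Directed acyclic graph of ontology terms.

    Edges are oriented child -> parent and carry a relation label
    (``is_a`` or ``part_of``).  Ancestor queries are memoized.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[tuple[str, str]]],
        namespace: str,
        alt_ids: Mapping[str, str] | None = None,
        names: Mapping[str, str] | None = None,
    ):
        terms: set[str] = set(parents)
        for plist in parents.values():
            for parent, _rel in plist:
                terms.add(parent)
        self._parents: dict[str, tuple[tuple[str, str], ...]] = {
            t: tuple(sorted(parents.get(t, ()))) for t in sorted(terms)
        }
        self.namespace = namespace
        self.alt_ids = dict(alt_ids or {})
        self.names = dict(names or {})
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._check_acyclic()

    # -- basic queries ---------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._parents)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self._parents.items() if not ps)

    def parents(self, term: str) -> tuple[tuple[str, str], ...]:
        """Direct (parent, relation) pairs of *term*."""
        return self._parents[term]

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield (child, parent, relation) for every retained edge."""
        for child in self._parents:
            for parent, rel in self._parents[child]:
                yield child, parent, rel

    def resolve(self, term: str) -> str:
        """Map an ``alt_id`` alias to its canonical term (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    # -- ancestors -------------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive parent closure of *term* over both edge types.

        Excludes *term* itself; the root's closure is empty.
        """
        if term not in self._parents:
            raise KeyError(f"unknown ontology term: {term!r}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        # iterative DFS with memoization; DAG guaranteed by construction
        out: set[str] = set()
        stack = [p for p, _ in self._parents[term]]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            hit = self._anc_cache.get(t)
            if hit is not None:
                out |= hit
                continue
            stack.extend(p for p, _ in self._parents[t])
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    # -- validation ------------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        g.add_edges_from((c, p) for c, p, _ in self.edges())
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(u for u, _ in cycle) + " -> " + cycle[-1][1]
            raise OntologyCycleError(f"ontology edges contain a cycle: {path}")

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._parents)
        for c, p, rel in self.edges():
            g.add_edge(c, p, key=rel)
        return g


def _prescan(text: str) -> None:
    """Cheap line-level validation so parse errors can name a line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if _STANZA_RE.match(stripped):
            continue
        if ":" not in stripped:
            raise OboParseError(
                f"malformed OBO content at line {lineno}: {stripped!r}"
            )


def load_obo(source: str | os.PathLike | TextIO, namespace: str = "biological_process") -> OntologyDAG:
    """Load an OBO file into an :class:`OntologyDAG`.

    Non-obsolete ``[Term]`` stanzas in *namespace* are retained; ``is_a``
    and ``relationship: part_of`` edges are kept and every other
    relationship type is discarded.  ``alt_id`` aliases are recorded on the
    returned DAG so they can be resolved to canonical terms.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    _prescan(text)
    logging.disable(logging.WARNING)  # obonet warns when optional headers are absent
    try:
        graph = obonet.read_obo(io.StringIO(text))
    except ValueError as exc:  # pragma: no cover - obonet's own validation
        raise OboParseError(f"OBO parse failure: {exc}") from exc
    finally:
        logging.disable(logging.NOTSET)

    default_ns = (graph.graph.get("default-namespace") or [namespace])[0]
    keep = {
        node
        for node, data in graph.nodes(data=True)
        if data.get("namespace", default_ns) == namespace
    }
    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in keep}
    for child, parent, rel in graph.edges(keys=True):
        if rel in RETAINED_RELATIONS and child in keep and parent in keep:
            parents[child].append((parent, rel))

    alt_ids: dict[str, str] = {}
    names: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if node not in keep:
            continue
        names[node] = data.get("name", node)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    dag = OntologyDAG(parents, namespace=namespace, alt_ids=alt_ids, names=names)
    if len(dag) and not dag.roots:  # pragma: no cover - implies a cycle, caught above
        raise OntologyCycleError("ontology has no root term")
    return dag
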