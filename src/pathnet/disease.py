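"""Disease mapping and module-clustering statistics.

Disease gene sets (OMIM/HPO-style annotations, restricted to diseases with
at least four genes) are mapped onto pathway nodes with one-sided Fisher
tests at raw p < 0.01.  A disease's "module" is its set of associated
nodes; the clustering hypothesis is that those nodes lie closer together
in the pruned network than random same-size node sets.  Closeness is
quantified by the multiset of unweighted shortest-path lengths between
module nodes (pairs split across components are excluded but counted), and
compared against a pooled null of 100 random node sets of equal size with
a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from pathnet.curation import PathwaySet
from pathnet.enrichment import hypergeom_tail
from pathnet.network import PathwayNetwork

# The name search used to pull cancer annotations out of a mixed
# disease/phenotype table.
CANCER_TERMS: tuple[str, ...] = (
    "cancer", "tumor", "tumour", "melanoma", "carcinoma",
    "leukemia", "lymphoma", "sarcoma",
)


@dataclass
class DiseaseAnnotation:
    id: str
    name: str
    genes: frozenset[str]
    kind: str = "disease"  # "disease" or "phenotype"


@dataclass
class DiseaseModuleResult:
    disease_id: str
    nodes: list[str]
    observed: Counter
    null: Counter
    excluded_pairs: int
    null_excluded_pairs: int
    ks_statistic: float
    ks_p: float
    clustered: bool  # observed mean path < null mean path


def load_disease_table(source: str | os.PathLike | TextIO) -> list[DiseaseAnnotation]:
    """Read a tab-delimited (disease id, disease name, gene) table.

    One gene per row; rows of one disease are aggregated.  An optional
    fourth column carries the kind label (disease/phenotype).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    rows: dict[str, dict] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"disease table line {lineno}: expected >= 3 columns")
        did, name, gene = fields[0], fields[1], fields[2]
        kind = fields[3] if len(fields) > 3 else "disease"
        entry = rows.setdefault(did, {"name": name, "genes": set(), "kind": kind})
        entry["genes"].add(gene)
    return [
        DiseaseAnnotation(id=did, name=v["name"], genes=frozenset(v["genes"]), kind=v["kind"])
        for did, v in sorted(rows.items())
    ]


def filter_min_genes(
    annotations: Iterable[DiseaseAnnotation], min_genes: int = 4
) -> list[DiseaseAnnotation]:
    """Keep diseases with at least *min_genes* genes (enrichment minimum)."""
    return [a for a in annotations if len(a.genes) >= min_genes]


def select_by_terms(
    annotations: Iterable[DiseaseAnnotation], terms: Sequence[str]
) -> list[DiseaseAnnotation]:
    """Case-insensitive substring search over disease names."""
    if not terms:
        raise ValueError("term list must be non-empty")
    lowered = [t.lower() for t in terms]
    return [a for a in annotations if any(t in a.name.lower() for t in lowered)]


def map_diseases(
    annotations: Iterable[DiseaseAnnotation],
    ps: PathwaySet,
    background: frozenset[str],
    alpha: float = 0.01,
) -> tuple[dict[str, list[str]], list[str]]:
    """Associate each disease with pathways at raw one-sided Fisher p < alpha.

    Disease genes are intersected with the background before testing (the
    disease-mapping threshold is applied to raw p, with no multiplicity
    correction).  Returns the disease -> pathway-id mapping and the ids of
    diseases skipped for lack of background overlap.
    """
    N = len(background)
    mapping: dict[str, list[str]] = {}
    skipped: list[str] = []
    for ann in annotations:
        query = ann.genes & background
        if not query:
            skipped.append(ann.id)
            continue
        n = len(query)
        hits = []
        for p in ps.pathways:
            carriers = p.genes & background
            K = len(carriers)
            if K == 0:
                continue
            k = len(query & carriers)
            if k == 0:
                continue
            if hypergeom_tail(k, K, n, N) < alpha:
                hits.append(p.id)
        mapping[ann.id] = sorted(hits)
    return mapping, skipped


def shortest_path_distribution(
    net: PathwayNetwork, node_set: Iterable[str]
) -> tuple[Counter, int]:
    """Shortest-path lengths between all node pairs sharing a component.

    Returns (multiset of hop counts, number of cross-component pairs
    excluded).  Distances are unweighted hop counts on the pruned graph.
    """
    nodes = sorted(set(node_set))
    unknown = [n for n in nodes if n not in net.graph]
    if unknown:
        raise KeyError(f"nodes not in network: {unknown[:3]}")
    if len(nodes) < 2:
        raise ValueError("need at least two nodes for a path distribution")
    dist: Counter = Counter()
    excluded = 0
    for i, u in enumerate(nodes):
        lengths = nx.single_source_shortest_path_length(net.graph, u)
        for v in nodes[i + 1 :]:
            if v in lengths:
                dist[lengths[v]] += 1
            else:
                excluded += 1
    return dist, excluded


def random_node_null(
    net: PathwayNetwork, k: int, reps: int = 100, seed: int = 0
) -> tuple[Counter, int]:
    """Pooled path-length null from *reps* uniform samples of k nodes."""
    nodes = sorted(net.graph.nodes)
    if k < 2:
        raise ValueError("node-set size must be >= 2")
    if k > len(nodes):
        raise ValueError(f"cannot sample {k} nodes from {len(nodes)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    pooled: Counter = Counter()
    excluded = 0
    for _ in range(reps):
        sample = rng.choice(len(nodes), size=k, replace=False)
        dist, exc = shortest_path_distribution(net, [nodes[i] for i in sample])
        pooled.update(dist)
        excluded += exc
    return pooled, excluded


def _expand(multiset: Counter) -> np.ndarray:
    return np.repeat(
        np.fromiter(multiset.keys(), dtype=float),
        np.fromiter(multiset.values(), dtype=int),
    )


def ks_cluster_test(observed: Counter, null: Counter) -> tuple[float, float, bool]:
    """Two-sample KS test of observed vs pooled-null path lengths.

    Returns (statistic, p, clustered) where *clustered* records whether the
    observed mean path length is below the null mean -- the direction that
    indicates module clustering.
    """
    if not observed or not null:
        raise ValueError("both path-length multisets must be non-empty")
    obs, nul = _expand(observed), _expand(null)
    res = ks_2samp(obs, nul)
    return float(res.statistic), float(res.pvalue), bool(obs.mean() < nul.mean())


def disease_module_analysis(
    net: PathwayNetwork,
    disease_nodes: Mapping[str, Sequence[str]],
    reps: int = 100,
    seed: int = 0,
) -> list[DiseaseModuleResult]:
    """Run the clustering test for every disease with >= 2 mapped nodes.

    Each disease gets its own derived seed so results are independent of
    dictionary ordering.
    """
    results: list[DiseaseModuleResult] = []
    ordered = sorted(disease_nodes)
    children = np.random.SeedSequence(seed).spawn(max(len(ordered), 1))
    for idx, did in enumerate(ordered):
        nodes = sorted(set(disease_nodes[did]))
        if len(nodes) < 2:
            continue
        observed, excl = shortest_path_distribution(net, nodes)
        dseed = int(children[idx].generate_state(1)[0] % (2**31))
        null, null_excl = random_node_null(net, k=len(nodes), reps=reps, seed=dseed)
        if not observed or not null:
            continue
        stat, p, clustered = ks_cluster_test(observed, null)
        results.append(
            DiseaseModuleResult(
                disease_id=did,
                nodes=nodes,
                observed=observed,
                null=null,
                excluded_pairs=excl,
                null_excluded_pairs=null_excl,
                ks_statistic=stat,
                ks_p=p,
                clustered=clustered,
            )
        )
    return results


def results_frame(results: Iterable[DiseaseModuleResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        obs, nul = _expand(r.observed), _expand(r.null)
        rows.append(
            {
                "disease": r.disease_id,
                "n_nodes": len(r.nodes),
                "mean_path": obs.mean(),
                "null_mean_path": nul.mean(),
                "ks_statistic": r.ks_statistic,
                "ks_p": r.ks_p,
                "clustered": r.clustered,
                "excluded_pairs": r.excluded_pairs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "disease", "n_nodes", "mean_path", "null_mean_path",
            "ks_statistic", "ks_p", "clustered", "excluded_pairs",
        ],
    )
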