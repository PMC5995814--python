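"""Disease mapping, name-based system selection, path statistics."""

import io
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from pathnet.curation import Pathway, PathwaySet
from pathnet.disease import (
    CANCER_TERMS,
    DiseaseAnnotation,
    filter_min_genes,
    ks_cluster_test,
    load_disease_table,
    map_diseases,
    random_node_null,
    select_by_terms,
    shortest_path_distribution,
)
from pathnet.network import PathwayNetwork, prune

from oracles import pairwise_distance_multiset


def test_disease_table_aggregates_rows():
    tsv = "D1\tsome disease\tG1\nD1\tsome disease\tG2\nD2\tother\tG3\tphenotype\n"
    anns = load_disease_table(io.StringIO(tsv))
    assert len(anns) == 2
    assert anns[0].genes == {"G1", "G2"}
    assert anns[1].kind == "phenotype"


def test_min_gene_filter():
    anns = [
        DiseaseAnnotation("D1", "a", frozenset({"G1", "G2", "G3", "G4"})),
        DiseaseAnnotation("D2", "b", frozenset({"G1"})),
    ]
    assert [a.id for a in filter_min_genes(anns, 4)] == ["D1"]


def test_cancer_term_selection():
    anns = [
        DiseaseAnnotation("D1", "Duodenal adenocarcinoma", frozenset({"G"})),
        DiseaseAnnotation("D2", "Familial hemiplegic migraine", frozenset({"G"})),
    ]
    out = select_by_terms(anns, CANCER_TERMS)
    assert [a.id for a in out] == ["D1"]


def test_term_selection_hand_verified_fixture():
    names = [
        ("D01", "synthetic sarcoma 1"),        # hit
        ("D02", "chronic asthma"),
        ("D03", "acute lymphoma"),             # hit
        ("D04", "Tumor of the eye"),           # hit
        ("D05", "melanoma, familial"),         # hit
        ("D06", "diabetes mellitus"),
        ("D07", "renal carcinoma"),            # hit
        ("D08", "migraine"),
        ("D09", "cystic fibrosis"),
        ("D10", "hepatomegaly"),
        ("D11", "elevated sweat chloride"),
        ("D12", "arthritis"),
    ]
    anns = [DiseaseAnnotation(d, n, frozenset({"G"})) for d, n in names]
    out = select_by_terms(anns, CANCER_TERMS)
    assert [a.id for a in out] == ["D01", "D03", "D04", "D05", "D07"]


def test_term_selection_idempotent_and_order_independent():
    anns = [
        DiseaseAnnotation("D1", "sarcoma", frozenset({"G"})),
        DiseaseAnnotation("D2", "migraine", frozenset({"G"})),
    ]
    once = select_by_terms(anns, CANCER_TERMS)
    twice = select_by_terms(once, CANCER_TERMS)
    assert [a.id for a in once] == [a.id for a in twice]
    shuffled = select_by_terms(anns, tuple(reversed(CANCER_TERMS)))
    assert {a.id for a in shuffled} == {a.id for a in once}


def test_exact_pathway_disease_maps_with_extreme_p():
    background = frozenset(f"G{i}" for i in range(50))
    target = frozenset(f"G{i}" for i in range(8))
    ps = PathwaySet(
        pathways=[
            Pathway("HIT", "match", target),
            Pathway("OTHER", "other", frozenset(f"G{i}" for i in range(30, 40))),
        ]
    )
    ann = DiseaseAnnotation("D1", "planted", target)
    mapping, skipped = map_diseases([ann], ps, background)
    assert mapping["D1"] == ["HIT"]
    assert skipped == []


def test_disease_without_background_overlap_is_skipped():
    background = frozenset({"G1", "G2"})
    ps = PathwaySet(pathways=[Pathway("P", "x", frozenset({"G1"}))])
    ann = DiseaseAnnotation("D1", "alien", frozenset({"Z1", "Z2", "Z3", "Z4"}))
    mapping, skipped = map_diseases([ann], ps, background)
    assert skipped == ["D1"]
    assert "D1" not in mapping


def test_uniform_null_disease_false_association_rate_is_small():
    """Null diseases (uniform gene draws) associate with ~alpha of pathways."""
    rng = np.random.default_rng(61)
    background = frozenset(f"G{i:03d}" for i in range(300))
    genes = sorted(background)
    pathways = [
        Pathway(f"P{i:02d}", "x", frozenset(rng.choice(genes, size=25, replace=False)))
        for i in range(40)
    ]
    ps = PathwaySet(pathways=pathways)
    anns = [
        DiseaseAnnotation(
            f"D{i:03d}", "null", frozenset(rng.choice(genes, size=20, replace=False))
        )
        for i in range(100)
    ]
    mapping, _ = map_diseases(anns, ps, background, alpha=0.01)
    rate = sum(len(v) for v in mapping.values()) / (100 * 40)
    assert rate <= 0.02


def _path_graph_net(n=5):
    edges = [(f"N{i}", f"N{i + 1}", 1.0) for i in range(n - 1)]
    return prune(edges, 0.5)


def test_adjacent_nodes_distance_one():
    net = _path_graph_net()
    dist, excluded = shortest_path_distribution(net, ["N0", "N1"])
    assert dist == Counter({1: 1})
    assert excluded == 0


def test_cross_component_pairs_excluded():
    net = prune([("A", "B", 1.0), ("C", "D", 1.0)], 0.5)
    dist, excluded = shortest_path_distribution(net, ["A", "C"])
    assert dist == Counter()
    assert excluded == 1


def test_path_graph_matches_bfs_oracle():
    net = _path_graph_net(5)
    nodes = [f"N{i}" for i in range(5)]
    dist, excluded = shortest_path_distribution(net, nodes)
    adjacency = {n: set(net.graph.neighbors(n)) for n in nodes}
    assert dist == pairwise_distance_multiset(adjacency, nodes)
    assert excluded == 0


def test_distribution_rejects_tiny_sets():
    net = _path_graph_net()
    with pytest.raises(ValueError):
        shortest_path_distribution(net, ["N0"])
    with pytest.raises(KeyError):
        shortest_path_distribution(net, ["N0", "MISSING"])


def test_null_with_k_equal_to_all_nodes_is_degenerate():
    net = _path_graph_net(4)
    pooled, _ = random_node_null(net, k=4, reps=3, seed=0)
    single, _ = shortest_path_distribution(net, [f"N{i}" for i in range(4)])
    assert pooled == Counter({k: 3 * v for k, v in single.items()})


def test_null_is_seed_reproducible():
    net = _path_graph_net(6)
    a, _ = random_node_null(net, k=3, reps=20, seed=11)
    b, _ = random_node_null(net, k=3, reps=20, seed=11)
    assert a == b


def test_null_rejects_oversized_k():
    net = _path_graph_net(4)
    with pytest.raises(ValueError):
        random_node_null(net, k=5)
    with pytest.raises(ValueError):
        random_node_null(net, k=1)


def _ring_of_cliques(n_cliques=10, clique_size=10):
    g = nx.ring_of_cliques(n_cliques, clique_size)
    g = nx.relabel_nodes(g, {n: f"N{n}" for n in g.nodes})
    return PathwayNetwork(graph=g, threshold=0.5)


def test_planted_module_shorter_than_null_mean():
    """Nodes inside one clique are closer than random same-size sets."""
    net = _ring_of_cliques()
    module = [f"N{i}" for i in range(6)]  # inside the first clique
    observed, _ = shortest_path_distribution(net, module)
    null, _ = random_node_null(net, k=6, reps=50, seed=3)
    obs_mean = sum(k * v for k, v in observed.items()) / sum(observed.values())
    null_mean = sum(k * v for k, v in null.items()) / sum(null.values())
    assert obs_mean < null_mean
    stat, p, clustered = ks_cluster_test(observed, null)
    assert clustered
    assert p < 0.01


def test_ks_extreme_separation():
    observed = Counter({1: 20})
    null = Counter({4: 500, 5: 300})
    stat, p, clustered = ks_cluster_test(observed, null)
    assert p < 1e-6
    assert clustered


def test_ks_rejects_empty_multisets():
    with pytest.raises(ValueError):
        ks_cluster_test(Counter(), Counter({1: 3}))


def test_operational_null_false_positive_rate_is_an_order_below_power(std_result):
    """Random node sets tested against their own pooled nulls: the
    false-positive rate at p<0.01 stays far below the planted-disease
    detection rate, though pair dependence within a set inflates it above
    the nominal level."""
    net = std_result.net
    nodes = sorted(net.graph.nodes)
    apsp = dict(nx.all_pairs_shortest_path_length(net.graph))

    def dist_of(sel):
        out = []
        for i, u in enumerate(sel):
            for v in sel[i + 1 :]:
                d = apsp[u].get(v)
                if d is not None:
                    out.append(d)
        return out

    rng = np.random.default_rng(71)
    from scipy.stats import ks_2samp

    hits = tested = 0
    for _ in range(200):
        obs = dist_of(list(rng.choice(nodes, size=6, replace=False)))
        null = []
        for _ in range(100):
            null.extend(dist_of(list(rng.choice(nodes, size=6, replace=False))))
        if not obs or not null:
            continue
        tested += 1
        hits += ks_2samp(obs, null).pvalue < 0.01
    assert tested >= 150
    assert hits / tested <= 0.1
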