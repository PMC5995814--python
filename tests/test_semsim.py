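"""Wang / Resnik term similarity and set-level aggregation."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathnet.annotations import EXPERIMENTAL, AnnotationTable
from pathnet.ontology import OntologyDAG, load_obo
from pathnet.semsim import (
    WangWeights,
    best_match_average,
    build_ic_map,
    make_termsim,
    pairwise_average,
    resnik_similarity,
    separation_report,
    wang_similarity,
    wang_svalues,
)

from oracles import wang_sim_brute

W = WangWeights()


def test_wang_weight_validation():
    with pytest.raises(ValueError):
        WangWeights(is_a=0.5, part_of=0.6)
    with pytest.raises(ValueError):
        WangWeights(is_a=1.0, part_of=0.6)


def test_svalues_of_root(chain_dag):
    sv = wang_svalues(chain_dag, "GO:0000001", W)
    assert sv.svalues == {"GO:0000001": 1.0}
    assert sv.sv == 1.0


def test_svalues_of_chain_leaf(chain_dag):
    sv = wang_svalues(chain_dag, "GO:0000003", W)
    assert sv.svalues == pytest.approx(
        {"GO:0000003": 1.0, "GO:0000002": 0.8, "GO:0000001": 0.64}
    )
    assert sv.sv == pytest.approx(2.44)


MIXED_OBO = """format-version: 1.2
default-namespace: biological_process
ontology: t

[Term]
id: ROOT
name: root
namespace: biological_process

[Term]
id: B
name: b
namespace: biological_process
is_a: ROOT

[Term]
id: C
name: c
namespace: biological_process
is_a: ROOT

[Term]
id: D
name: d
namespace: biological_process
is_a: B
relationship: part_of C

[Term]
id: A
name: a
namespace: biological_process
is_a: D
relationship: part_of B

[Term]
id: E
name: e
namespace: biological_process
is_a: C

[Term]
id: F
name: f
namespace: biological_process
is_a: D

[Term]
id: G
name: g
namespace: biological_process
is_a: E
"""


@pytest.fixture
def mixed_dag():
    return load_obo(io.StringIO(MIXED_OBO))


def _weighted_parents(dag, weights=W):
    return {
        c: [(p, weights.of(rel)) for p, rel in dag.parents(c)] for c in dag.terms
    }


def test_svalues_match_exhaustive_path_enumeration(mixed_dag):
    """Max-over-paths brute force on an 8-term DAG with part_of edges."""
    wp = _weighted_parents(mixed_dag)
    from oracles import all_paths_svalue

    for term in sorted(mixed_dag.terms):
        ours = wang_svalues(mixed_dag, term, W)
        brute = all_paths_svalue(wp, term)
        assert ours.svalues == pytest.approx(brute)


def test_wang_similarity_matches_brute_force_all_pairs(mixed_dag):
    wp = _weighted_parents(mixed_dag)
    terms = sorted(mixed_dag.terms)
    for a in terms:
        for b in terms:
            assert wang_similarity(mixed_dag, a, b, W) == pytest.approx(
                wang_sim_brute(wp, a, b)
            )


def test_wang_self_similarity_is_one(mixed_dag):
    for t in mixed_dag.terms:
        assert wang_similarity(mixed_dag, t, t, W) == pytest.approx(1.0)


def test_two_depth2_leaves_sharing_only_root():
    obo = """format-version: 1.2
default-namespace: biological_process
ontology: t

[Term]
id: R
name: r
namespace: biological_process

[Term]
id: B1
name: b1
namespace: biological_process
is_a: R

[Term]
id: B2
name: b2
namespace: biological_process
is_a: R

[Term]
id: L1
name: l1
namespace: biological_process
is_a: B1

[Term]
id: L2
name: l2
namespace: biological_process
is_a: B2
"""
    dag = load_obo(io.StringIO(obo))
    # S-values of each leaf: {leaf: 1, parent: .8, root: .64}; only the root
    # is shared: (0.64 + 0.64) / (2.44 + 2.44)
    assert wang_similarity(dag, "L1", "L2", W) == pytest.approx(1.28 / 4.88)


def test_siblings_closer_than_distant_cousins(mixed_dag):
    sib = wang_similarity(mixed_dag, "A", "F", W)   # both under D
    cous = wang_similarity(mixed_dag, "A", "G", W)  # shared only near root
    assert sib > cous


def test_wang_decays_along_chains(chain_dag):
    near = wang_similarity(chain_dag, "GO:0000003", "GO:0000002", W)
    far = wang_similarity(chain_dag, "GO:0000003", "GO:0000001", W)
    assert near > far


def _ic_table(counts, total):
    """AnnotationTable whose term->gene counts match *counts* exactly."""
    entries: dict[str, set] = {f"g{i}": set() for i in range(total)}
    for term, c in counts.items():
        for i in range(c):
            entries[f"g{i}"].add((term, EXPERIMENTAL))
    return AnnotationTable(
        entries={g: frozenset(v) for g, v in entries.items() if v}, propagated=True
    )


def test_resnik_root_only_ancestor_scores_zero(mixed_dag):
    # all genes carry ROOT; B and C carried by separate halves
    table = _ic_table({"ROOT": 10, "B": 5, "C": 5, "E": 2, "D": 3}, 10)
    ic = build_ic_map(table)
    assert resnik_similarity(mixed_dag, ic, "B", "C") == 0.0


def test_resnik_rarest_term_self_similarity_is_one(mixed_dag):
    table = _ic_table({"ROOT": 10, "B": 6, "D": 3, "A": 1}, 10)
    ic = build_ic_map(table)
    assert resnik_similarity(mixed_dag, ic, "A", "A") == pytest.approx(1.0)


def test_resnik_matches_enumeration_on_hand_assigned_counts():
    obo = """format-version: 1.2
default-namespace: biological_process
ontology: t

[Term]
id: R
name: r
namespace: biological_process

[Term]
id: X
name: x
namespace: biological_process
is_a: R

[Term]
id: Y
name: y
namespace: biological_process
is_a: R

[Term]
id: P
name: p
namespace: biological_process
is_a: X

[Term]
id: Q
name: q
namespace: biological_process
is_a: X
"""
    dag = load_obo(io.StringIO(obo))
    counts = {"R": 20, "X": 8, "Y": 12, "P": 2, "Q": 4}
    table = _ic_table(counts, 20)
    ic = build_ic_map(table)
    # common ancestors of P and Q: {X, R}; MICA = X with p = 8/20
    expected = -math.log(8 / 20) / -math.log(2 / 20)
    assert resnik_similarity(dag, ic, "P", "Q") == pytest.approx(expected)


def test_resnik_unannotated_term_rejected(mixed_dag):
    table = _ic_table({"ROOT": 5, "B": 2}, 5)
    ic = build_ic_map(table)
    with pytest.raises(ValueError, match="no annotated genes"):
        resnik_similarity(mixed_dag, ic, "B", "G")


def test_resnik_invariant_to_duplicating_every_gene(mixed_dag):
    counts = {"ROOT": 8, "B": 4, "D": 2, "C": 3}
    t1 = _ic_table(counts, 8)
    t2 = _ic_table({k: 2 * v for k, v in counts.items()}, 16)
    ic1, ic2 = build_ic_map(t1), build_ic_map(t2)
    assert resnik_similarity(mixed_dag, ic1, "B", "D") == pytest.approx(
        resnik_similarity(mixed_dag, ic2, "B", "D")
    )


# ---------------------------------------------------------------- set level


def _tabulated(table):
    def sim(a, b):
        return 1.0 if a == b else table.get((a, b), table.get((b, a), 0.0))

    return sim


def test_single_term_sets_reduce_to_termsim():
    sim = _tabulated({("x", "y"): 0.37})
    assert pairwise_average({"x"}, {"y"}, sim) == pytest.approx(0.37)
    assert best_match_average({"x"}, {"y"}, sim) == pytest.approx(0.37)


def test_identical_singleton_sets():
    sim = _tabulated({})
    assert pairwise_average({"t"}, {"t"}, sim) == 1.0
    assert best_match_average({"t"}, {"t"}, sim) == 1.0


def test_identical_two_term_profiles_pairwise_half_bma_one():
    """Two pathways annotated {t1, t2}, cross-similarity 0: pairwise
    average 0.5 but best-match average 1."""
    sim = _tabulated({("t1", "t2"): 0.0})
    A = B = {"t1", "t2"}
    assert pairwise_average(A, B, sim) == pytest.approx(0.5)
    assert best_match_average(A, B, sim) == pytest.approx(1.0)


def test_aggregations_match_direct_summation_oracle():
    rng = np.random.default_rng(21)
    A = [f"a{i}" for i in range(3)]
    B = [f"b{i}" for i in range(4)]
    table = {(a, b): float(rng.uniform(0, 1)) for a in A for b in B}
    sim = _tabulated(table)
    direct_mean = sum(table[(a, b)] for a in A for b in B) / 12
    assert pairwise_average(A, B, sim) == pytest.approx(direct_mean)
    row = sum(max(table[(a, b)] for b in B) for a in A)
    col = sum(max(table[(a, b)] for a in A) for b in B)
    assert best_match_average(A, B, sim) == pytest.approx((row + col) / 7)


def test_empty_sets_rejected():
    sim = _tabulated({})
    with pytest.raises(ValueError):
        pairwise_average(set(), {"t"}, sim)
    with pytest.raises(ValueError):
        best_match_average({"t"}, set(), sim)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_bma_dominates_pairwise_and_is_symmetric(data):
    n_a = data.draw(st.integers(1, 4))
    n_b = data.draw(st.integers(1, 4))
    A = [f"a{i}" for i in range(n_a)]
    B = [f"b{i}" for i in range(n_b)]
    vals = {}
    universe = A + B
    for i, x in enumerate(universe):
        for y in universe[i + 1 :]:
            vals[(x, y)] = data.draw(
                st.floats(min_value=0, max_value=1, allow_nan=False)
            )
    sim = _tabulated(vals)
    pw, bma = pairwise_average(A, B, sim), best_match_average(A, B, sim)
    assert 0 <= pw <= 1 and 0 <= bma <= 1
    assert bma >= pw - 1e-12
    assert pairwise_average(B, A, sim) == pytest.approx(pw)
    assert best_match_average(B, A, sim) == pytest.approx(bma)
    assert best_match_average(A, A, sim) == pytest.approx(1.0)


def test_cached_termsim_is_order_independent(mixed_dag):
    s1 = make_termsim(mixed_dag, "wang", W)
    s2 = make_termsim(mixed_dag, "wang", W)
    pairs = [("A", "G"), ("G", "A"), ("B", "C"), ("A", "G")]
    assert [s1(a, b) for a, b in pairs] == [s2(a, b) for a, b in reversed(pairs)][::-1]


def test_separation_identical_profiles_have_equal_distributions(mixed_dag):
    table = _ic_table({"ROOT": 10, "B": 5, "C": 5, "D": 3, "A": 2, "E": 2, "F": 1, "G": 1}, 10)
    ic = build_ic_map(table)
    sets = {"P1": {"A", "F"}, "P2": {"A", "F"}}
    rep = separation_report(sets, mixed_dag, ic)
    r = rep["wang_bma"]
    assert r.within == pytest.approx([1.0, 1.0])
    assert r.between == pytest.approx([1.0])


def test_separation_disjoint_branches_give_low_between(std_result):
    """Profiles drawn from different ontology branches barely resemble
    each other, so the between-profile mass sits well below within."""
    term_sets = {
        p.pathway_id: p.terms for p in std_result.profiles[:20] if p.terms
    }
    ic = build_ic_map(std_result.table)
    rep = separation_report(term_sets, std_result.dag, ic)
    for key in ("wang_bma", "wang_pairwise"):
        assert rep[key].mean_difference > 0


def test_wang_bma_separates_at_least_as_well_as_resnik_pairwise(std_result):
    """The qualitative metric comparison on the standard fixture: Wang BMA
    gives the clearest within- vs between-pathway separation."""
    term_sets = {p.pathway_id: p.terms for p in std_result.profiles if p.terms}
    ic = build_ic_map(std_result.table)
    rep = separation_report(term_sets, std_result.dag, ic)
    assert rep["wang_bma"].ks_statistic >= rep["resnik_pairwise"].ks_statistic
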