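"""Pair mining, association rules, and the co-prescription network."""

from itertools import combinations, product

import pytest
from hypothesis import given, settings, strategies as st

from herbmine import (
    IntegrityError,
    association_rules,
    build_network,
    compute_rfc,
    core_ranking,
    count_pairs,
    high_frequency_pairs,
)
from herbmine.mining import write_edgelist, write_graphml

from conftest import (
    make_corpus,
    naive_confidence_one,
    naive_fc,
    naive_pair_support,
)


def pairs_as_dict(stats):
    return {
        (r.material_a, r.material_b): r.support for r in stats.itertuples(index=False)
    }


def test_hand_enumerated_pair_counts(tiny_corpus):
    stats = count_pairs(tiny_corpus)
    d = pairs_as_dict(stats)
    assert d == {("A", "B"): 2, ("A", "C"): 1}
    row = stats.set_index(["material_a", "material_b"]).loc[("A", "B")]
    assert row["conf_b_to_a"] == 1.0  # B -> A holds in both prescriptions of B
    assert row["conf_a_to_b"] == pytest.approx(2 / 3)


def test_support_bounded_by_member_citations(toy):
    stats = count_pairs(toy)
    for r in stats.itertuples(index=False):
        assert r.support <= min(r.fc_a, r.fc_b)


def test_miner_equals_oracle_exhaustively():
    """Every corpus of up to 3 nonempty prescriptions over 3 materials."""
    universe = ["a", "b", "c"]
    subsets = [
        set(s)
        for r in range(1, 4)
        for s in combinations(universe, r)
    ]
    for n in (1, 2, 3):
        for combo in product(subsets, repeat=n):
            sets = [set(s) for s in combo]
            d = pairs_as_dict(count_pairs(make_corpus(sets)))
            assert d == naive_pair_support(sets)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    st.lists(
        st.frozensets(st.sampled_from("abcdef"), min_size=1, max_size=6),
        min_size=1,
        max_size=6,
    )
)
def test_miner_equals_oracle_on_random_corpora(sets):
    sets = [set(s) for s in sets]
    assert pairs_as_dict(count_pairs(make_corpus(sets))) == naive_pair_support(sets)


def test_threshold_strictness_boundary():
    sets = (
        [{"a", "b"}] * 42 + [{"c", "d"}] * 41 + [{"e", "f"}] * 40
    )
    stats = count_pairs(make_corpus(sets))
    assert len(high_frequency_pairs(stats, 41, strict=True)) == 1
    assert len(high_frequency_pairs(stats, 41, strict=False)) == 2
    assert list(high_frequency_pairs(stats, 0)["support"]) == [42, 41, 40]


def test_threshold_raising_never_adds_pairs(toy):
    stats = count_pairs(toy)
    prev = len(stats)
    for t in range(0, 6):
        cur = len(high_frequency_pairs(stats, t))
        assert cur <= prev
        prev = cur


def test_empty_stats_passthrough():
    stats = count_pairs(make_corpus([{"solo"}]))
    assert len(stats) == 0
    assert len(high_frequency_pairs(stats, 0)) == 0
    assert len(association_rules(stats, 0, 0.0)) == 0


# ------------------------------------------------------------ rules

def test_rule_confidence_arithmetic():
    sets = [{"A", "B"}] * 3 + [{"A"}]
    rules = association_rules(count_pairs(make_corpus(sets)), 1, 0.5)
    by_dir = {(r.antecedent, r.consequent): r.confidence
              for r in rules.itertuples(index=False)}
    assert by_dir[("A", "B")] == 0.75
    assert by_dir[("B", "A")] == 1.0


def test_confidence_one_soundness_by_direct_scan(toy):
    sets = [set(p.materials) for p in toy.prescriptions]
    rules = association_rules(count_pairs(toy), 1, 1.0)
    emitted = {(r.antecedent, r.consequent) for r in rules.itertuples(index=False)}
    universe = sorted(set().union(*sets))
    for a in universe:
        for b in universe:
            if a == b:
                continue
            # pairs never co-occurring are not rule candidates
            expected = naive_confidence_one(sets, a, b) and any(
                a in s and b in s for s in sets
            )
            assert ((a, b) in emitted) == expected


def test_counterexample_destroys_confidence_one():
    sets = [{"A", "B"}] * 5
    stats = count_pairs(make_corpus(sets))
    assert ("A", "B") in {
        (r.antecedent, r.consequent)
        for r in association_rules(stats, 1, 1.0).itertuples(index=False)
    }
    stats2 = count_pairs(make_corpus(sets + [{"A"}]))
    assert ("A", "B") not in {
        (r.antecedent, r.consequent)
        for r in association_rules(stats2, 1, 1.0).itertuples(index=False)
    }


def test_min_support_above_max_gives_no_rules(toy):
    stats = count_pairs(toy)
    assert len(association_rules(stats, int(stats["support"].max()) + 1, 0.0)) == 0


# ------------------------------------------------------------ network

def test_network_matches_brute_force_on_toy(toy):
    stats = count_pairs(toy)
    rfc = compute_rfc(toy)
    net = build_network(stats, rfc, edge_threshold=1, node_cutoff=0.2)
    sets = [set(p.materials) for p in toy.prescriptions]
    expected = {
        pair: s for pair, s in naive_pair_support(sets).items() if s > 1
    }
    got = {
        (r.material_a, r.material_b): r.weight
        for r in net.edges.itertuples(index=False)
    }
    assert got == expected


def test_infinite_threshold_gives_edgeless_graph(toy):
    net = build_network(count_pairs(toy), compute_rfc(toy), edge_threshold=10**9)
    assert net.graph.number_of_edges() == 0
    assert net.graph.number_of_nodes() > 0


def test_node_cutoff_restricts_to_frequent(toy):
    rfc = compute_rfc(toy)
    restricted = build_network(count_pairs(toy), rfc, 0, node_cutoff=0.5)
    assert set(restricted.nodes) <= set(rfc["material_id"])
    full = build_network(count_pairs(toy), rfc, 0, node_cutoff=None)
    assert set(full.nodes) == set(rfc["material_id"])


def test_network_rejects_unknown_materials(toy):
    stats = count_pairs(toy)
    rfc = compute_rfc(toy)
    rfc = rfc[rfc["material_id"] != "angelica_sinensis"]
    with pytest.raises(IntegrityError, match="angelica_sinensis"):
        build_network(stats, rfc)


def test_core_ranking_order_and_k(toy):
    net = build_network(count_pairs(toy), compute_rfc(toy), edge_threshold=0)
    ranking = core_ranking(net)
    assert ranking[0] == "angelica_sinensis"
    fcs = [net.graph.nodes[m]["fc"] for m in ranking]
    assert fcs == sorted(fcs, reverse=True)
    assert core_ranking(net, k=2) == ranking[:2]
    with pytest.warns(UserWarning, match="exceeds"):
        assert core_ranking(net, k=100) == ranking
    with pytest.raises(ValueError):
        core_ranking(net, k=0)


def test_single_node_network_ranks_itself():
    corpus = make_corpus([{"only"}])
    net = build_network(count_pairs(corpus), compute_rfc(corpus))
    assert core_ranking(net) == ["only"]


def test_network_exports(toy, tmp_path):
    import networkx as nx

    net = build_network(count_pairs(toy), compute_rfc(toy), edge_threshold=0)
    write_graphml(net, tmp_path / "n.graphml")
    write_edgelist(net, tmp_path / "n.tsv")
    g = nx.read_graphml(tmp_path / "n.graphml")
    assert g.number_of_nodes() == net.graph.number_of_nodes()
    assert g.number_of_edges() == net.graph.number_of_edges()
    assert (tmp_path / "n.tsv").read_text().startswith("material_a\tmaterial_b\tweight")
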