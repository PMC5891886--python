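import math
from itertools import permutations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stromanet import netdiff
from stromanet.netdiff import (
    CorrelationEdge,
    EdgeSet,
    EndpointMatrix,
    build_network,
    detect_subgroups,
    export_network,
    read_network,
    shared_and_exclusive,
    significant_edges,
    spearman_edge,
)


def make_edge_set(pairs, group="high", compartment="epithelium", rho=0.9):
    edges = {}
    for a, b in pairs:
        a, b = sorted((a, b))
        edges[(a, b)] = CorrelationEdge(a, b, rho, 0.001, 9)
    return EdgeSet(group, compartment, edges)


class TestSpearmanEdge:
    def test_strictly_monotone(self):
        x = np.arange(1, 10)
        rho, p, n = spearman_edge(x, 2 * x)
        assert rho == pytest.approx(1.0)
        assert n == 9
        assert p == pytest.approx(2 / math.factorial(9))

    def test_reversal(self):
        rho, p, _ = spearman_edge([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_too_few_pairs_missing(self):
        assert spearman_edge([1, 2, 3], [3, 1, 2]) is None
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, np.nan, 3.0, 5.0, 7.0]
        assert spearman_edge(x, y) is None  # only 3 complete pairs

    def test_zero_variance_missing(self):
        assert spearman_edge([1, 1, 1, 1, 1], [1, 2, 3, 4, 5]) is None

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, 3.0, 4.0, np.nan, 6.0]
        y = [1.0, 4.0, 9.0, 16.0, 25.0, 36.0]
        rho, _, n = spearman_edge(x, y)
        assert n == 5
        assert rho == pytest.approx(1.0)

    def test_permutation_p_of_perfect_correlation(self):
        rho, p, _ = spearman_edge([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], method="permutation")
        assert p == pytest.approx(2 / 120)

    @given(st.permutations(list(range(1, 6))))
    def test_spearman_invariant_under_monotone_transform(self, perm):
        x = np.arange(1, 6, dtype=float)
        y = np.asarray(perm, float)
        r1 = spearman_edge(x, y)
        r2 = spearman_edge(np.exp(x), y**3)  # strictly increasing transforms
        if r1 is None:
            assert r2 is None
        else:
            assert r1[0] == pytest.approx(r2[0])
            r3 = spearman_edge(-x, y)
            assert r3[0] == pytest.approx(-r1[0])


class TestSignificantEdges:
    def test_all_pairs_evaluated_for_30_endpoints(self):
        rng = np.random.default_rng(0)
        mat = EndpointMatrix(
            "high", "stroma",
            [f"c{i}" for i in range(9)],
            [f"P{i:02d}" for i in range(30)],
            rng.lognormal(0, 1, (9, 30)),
        )
        es = significant_edges(mat)
        assert es.n_pairs_evaluated == math.comb(30, 2) == 435
        assert len(es) <= 435

    def test_duplicated_column_is_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 9)
        values = np.column_stack([x, x, rng.normal(0, 1, 9)])
        mat = EndpointMatrix("high", "stroma", [f"c{i}" for i in range(9)],
                             ["A", "B", "C"], values)
        es = significant_edges(mat)
        assert ("A", "B") in es.edges
        assert es.edges[("A", "B")].rho == pytest.approx(1.0)

    def test_joint_rule_both_conditions_enforced(self):
        # y is a permutation of 1..9 with sum of squared rank differences 28,
        # i.e. sample rho = 1 - 28/120 ~= 0.767 >= 0.75 but t-approx p > 0.01
        x = np.arange(1, 10, dtype=float)
        y = np.array([4, 1, 2, 3, 8, 5, 6, 9, 7], dtype=float)
        rho, p, _ = spearman_edge(x, y)
        assert rho == pytest.approx(1 - 28 / 120)
        assert rho >= 0.75
        assert p > 0.01
        mat = EndpointMatrix("high", "stroma", [f"c{i}" for i in range(9)],
                             ["A", "B"], np.column_stack([x, y]))
        assert len(significant_edges(mat)) == 0

    def test_negative_rho_excluded_by_default_included_with_abs(self):
        x = np.arange(1, 10, dtype=float)
        mat = EndpointMatrix("high", "stroma", [f"c{i}" for i in range(9)],
                             ["A", "B"], np.column_stack([x, -x]))
        assert len(significant_edges(mat)) == 0
        es = significant_edges(mat, abs_rho=True)
        assert es.edges[("A", "B")].rho == pytest.approx(-1.0)

    def test_missing_data_uses_pairwise_complete(self):
        x = np.arange(1, 11, dtype=float)
        values = np.column_stack([x, x, x])
        values[0, 2] = np.nan
        mat = EndpointMatrix("high", "stroma", [f"c{i}" for i in range(10)],
                             ["A", "B", "C"], values)
        es = significant_edges(mat)
        assert es.edges[("A", "B")].n_obs == 10
        assert es.edges[("A", "C")].n_obs == 9

    def test_determinism(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(0, 1, (9, 12))
        mat = EndpointMatrix("high", "stroma", [f"c{i}" for i in range(9)],
                             [f"P{i}" for i in range(12)], values)
        assert significant_edges(mat).edges == significant_edges(mat).edges


class TestSharedExclusive:
    def test_identical_sets(self):
        a = make_edge_set([("A", "B"), ("B", "C")])
        b = make_edge_set([("A", "B"), ("B", "C")], group="low")
        shared, ex_a, ex_b = shared_and_exclusive(a, b)
        assert shared == {("A", "B"), ("B", "C")}
        assert len(ex_a) == len(ex_b) == 0

    def test_disjoint_sets(self):
        a = make_edge_set([("A", "B")])
        b = make_edge_set([("C", "D")], group="low")
        shared, ex_a, ex_b = shared_and_exclusive(a, b)
        assert shared == set()
        assert ex_a.pairs == {("A", "B")}
        assert ex_b.pairs == {("C", "D")}

    def test_compartment_mismatch(self):
        a = make_edge_set([("A", "B")], compartment="epithelium")
        b = make_edge_set([("A", "B")], compartment="stroma")
        with pytest.raises(ValueError, match="compartment"):
            shared_and_exclusive(a, b)

    @given(st.data())
    def test_partition_identity(self, data):
        labels = [f"P{i}" for i in range(8)]
        all_pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
        pa = data.draw(st.sets(st.sampled_from(all_pairs)))
        pb = data.draw(st.sets(st.sampled_from(all_pairs)))
        a = make_edge_set(pa)
        b = make_edge_set(pb, group="low")
        shared, ex_a, ex_b = shared_and_exclusive(a, b)
        assert len(shared) + len(ex_a) == len(a.edges)
        assert len(shared) + len(ex_b) == len(b.edges)
        assert len(shared) + len(ex_a) + len(ex_b) == len(a.pairs | b.pairs)
        assert not shared & ex_a.pairs and not shared & ex_b.pairs

    def test_exclusive_edges_keep_their_groups_rho(self):
        a = make_edge_set([("A", "B"), ("C", "D")], rho=0.8)
        b = make_edge_set([("A", "B")], group="low", rho=0.95)
        _, ex_a, _ = shared_and_exclusive(a, b)
        assert ex_a.edges[("C", "D")].rho == 0.8


class TestNetwork:
    def test_star_degrees(self):
        net = build_network(make_edge_set([("A", "B"), ("A", "C"), ("A", "D")]))
        assert net.graph.nodes["A"]["degree"] == 3
        assert all(net.graph.nodes[x]["degree"] == 1 for x in "BCD")

    def test_empty_set_gives_empty_graph(self):
        net = build_network(make_edge_set([]))
        assert net.graph.number_of_nodes() == 0
        labels, n = detect_subgroups(net, seed=0)
        assert labels == {} and n == 0

    @given(st.data())
    def test_handshake_identity(self, data):
        labels = [f"P{i}" for i in range(10)]
        all_pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
        pairs = data.draw(st.sets(st.sampled_from(all_pairs)))
        net = build_network(make_edge_set(pairs))
        degrees = [d for _, d in net.graph.degree]
        assert sum(degrees) == 2 * len(pairs)

    def test_single_clique_one_subgroup(self):
        pairs = [(a, b) for i, a in enumerate("ABCD") for b in "ABCD"[i + 1:]]
        net = build_network(make_edge_set(pairs))
        _, n = detect_subgroups(net, seed=0)
        assert n == 1

    def test_three_disjoint_cliques_three_subgroups(self):
        pairs = []
        for block in ("ABCDE", "FGHIJ", "KLMNO"):
            pairs += [(a, b) for i, a in enumerate(block) for b in block[i + 1:]]
        net = build_network(make_edge_set(pairs))
        labels, n = detect_subgroups(net, seed=0)
        assert n == 3
        assert sorted(set(labels.values())) == [0, 1, 2]

    def test_planted_blocks_recovered(self):
        # three dense 6-node blocks (within-block edge prob 0.9, between 0.05)
        rng = np.random.default_rng(0)
        nodes = [f"N{i:02d}" for i in range(18)]
        hits = 0
        for seed in range(100):
            pairs = []
            for i in range(18):
                for j in range(i + 1, 18):
                    p = 0.9 if i // 6 == j // 6 else 0.05
                    if rng.random() < p:
                        pairs.append((nodes[i], nodes[j]))
            net = build_network(make_edge_set(pairs, rho=0.8))
            _, n = detect_subgroups(net, seed=seed)
            hits += n == 3
        assert hits >= 95

    def test_subgroups_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        nodes = [f"N{i}" for i in range(15)]
        pairs = {
            tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(40)
        }
        l1, _ = detect_subgroups(build_network(make_edge_set(pairs)), seed=11)
        l2, _ = detect_subgroups(build_network(make_edge_set(pairs)), seed=11)
        assert l1 == l2


class TestExport:
    @pytest.mark.parametrize("fmt", ["gexf", "graphml"])
    def test_roundtrip_preserves_structure(self, tmp_path, fmt):
        rng = np.random.default_rng(2)
        nodes = [f"N{i:02d}" for i in range(20)]
        pairs = {
            tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(40)
        }
        net = build_network(make_edge_set(pairs, rho=0.87))
        detect_subgroups(net, seed=0)
        path = tmp_path / f"net.{fmt}"
        export_network(net, path, format=fmt)
        back = read_network(path, format=fmt)
        assert back.number_of_nodes() == net.graph.number_of_nodes()
        assert back.number_of_edges() == net.graph.number_of_edges()
        for a, b, data in net.graph.edges(data=True):
            assert back.edges[a, b]["weight"] == pytest.approx(data["weight"])
        for n, data in net.graph.nodes(data=True):
            assert back.nodes[n]["degree"] == data["degree"]
            assert back.nodes[n]["community"] == data["community"]

    def test_empty_network_roundtrip(self, tmp_path):
        net = build_network(make_edge_set([]))
        path = tmp_path / "empty.gexf"
        export_network(net, path)
        assert read_network(path).number_of_nodes() == 0

    def test_unknown_format(self, tmp_path):
        net = build_network(make_edge_set([("A", "B")]))
        with pytest.raises(ValueError, match="format"):
            export_network(net, tmp_path / "x.dot", format="dot")


def test_canonical_edge_order_enforced():
    with pytest.raises(ValueError):
        CorrelationEdge("B", "A", 0.9, 0.001, 9)
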