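import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viromet.metabnet import (
    MetabolismNetwork,
    build_network,
    compare_degree_distributions,
    compare_distance_distributions,
    distance_shells,
    export_network,
    import_network,
    mhg_pvalue_sampled,
    mhg_statistic_and_pvalue,
    rank_by_degree,
    shell_enrichment,
)
from viromet.pathways import PathwayDef, PathwayUniverse


def pathway(pid, substrates=(), products=(), members=("K1",)):
    return PathwayDef(pid, pid, frozenset(members), frozenset(substrates), frozenset(products))


def star_network(enriched=()):
    g = nx.Graph()
    g.add_edges_from([("hub", f"leaf{i}") for i in range(4)])
    return MetabolismNetwork(graph=g, enriched=frozenset(enriched))


class TestBuildNetwork:
    def test_shared_compound_creates_single_edge(self):
        uni = PathwayUniverse([pathway("A", products=["c1"]), pathway("B", substrates=["c1"])])
        net = build_network(uni)
        assert set(net.graph.edges) == {("A", "B")} or set(net.graph.edges) == {("B", "A")}
        assert net.n_edges == 1

    def test_disjoint_compounds_no_edges(self):
        uni = PathwayUniverse(
            [pathway("A", substrates=["c1"], products=["c2"]),
             pathway("B", substrates=["c3"], products=["c4"])]
        )
        assert build_network(uni).n_edges == 0

    def test_excluded_compounds_ignored(self):
        uni = PathwayUniverse([pathway("A", products=["c1"]), pathway("B", substrates=["c1"])])
        assert build_network(uni, exclude_compounds=["c1"]).n_edges == 0

    def test_matches_pairwise_brute_force(self, small_dataset):
        uni = small_dataset.universe
        net = build_network(uni)
        expected = set()
        pws = list(uni)
        for a, b in itertools.combinations(pws, 2):
            if (a.products & b.substrates) or (b.products & a.substrates):
                expected.add(frozenset((a.pathway_id, b.pathway_id)))
        assert {frozenset(e) for e in net.graph.edges} == expected

    def test_degree_sum_is_twice_edges(self, small_dataset):
        net = build_network(small_dataset.universe)
        assert sum(d for _, d in net.graph.degree) == 2 * net.n_edges


class TestRankByDegree:
    def test_star_hub_first(self):
        order, vector = rank_by_degree(star_network(enriched=["hub"]))
        assert order[0] == "hub"
        assert vector[0] == 1 and vector.sum() == 1

    def test_isolated_nodes_rank_lexicographically(self):
        g = nx.Graph()
        g.add_nodes_from(["b", "a", "c"])
        order, _ = rank_by_degree(MetabolismNetwork(graph=g))
        assert order == ["a", "b", "c"]

    def test_order_consistent_with_recounted_degrees(self, small_dataset):
        net = build_network(small_dataset.universe)
        order, _ = rank_by_degree(net)
        degrees = [net.graph.degree(v) for v in order]
        assert degrees == sorted(degrees, reverse=True)
        assert sorted(order) == sorted(net.graph.nodes)


def oracle_mhg(vec):
    """Independent mHG oracle: statistic from first principles and the
    p-value by enumerating every distinct arrangement."""
    L, B = len(vec), sum(vec)

    def tail(l, b):
        num = sum(
            math.comb(B, i) * math.comb(L - B, l - i)
            for i in range(b, min(l, B) + 1)
        )
        return Fraction(num, math.comb(L, l))

    def stat(v):
        b = 0
        best = Fraction(1)
        for l in range(1, L + 1):
            b += v[l - 1]
            best = min(best, tail(l, b))
        return best

    observed = stat(vec)
    hits = total = 0
    for ones in itertools.combinations(range(L), B):
        arrangement = [1 if i in ones else 0 for i in range(L)]
        total += 1
        if stat(arrangement) <= observed:
            hits += 1
    return observed, Fraction(hits, total)


class TestMHG:
    def test_enumerated_four_vector(self):
        res = mhg_statistic_and_pvalue([1, 1, 0, 0])
        assert res.mhg_statistic == pytest.approx(1 / 6)
        assert res.cutoff_index == 2
        assert res.p_value == pytest.approx(1 / 6)

    def test_all_ones_degenerate(self):
        res = mhg_statistic_and_pvalue([1, 1, 1])
        assert res.mhg_statistic == 1.0 and res.p_value == 1.0

    def test_all_zero_vector_raises(self):
        with pytest.raises(ValueError):
            mhg_statistic_and_pvalue([0, 0, 0])

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_dp_matches_exhaustive_permutations_length8(self, k):
        for ones in itertools.combinations(range(8), k):
            vec = [1 if i in ones else 0 for i in range(8)]
            stat, p = oracle_mhg(vec)
            res = mhg_statistic_and_pvalue(vec)
            assert res.mhg_statistic == pytest.approx(float(stat), abs=1e-14)
            assert res.p_value == pytest.approx(float(p), abs=1e-12)

    def test_invariant_to_appended_zeros(self):
        base = [1, 0, 1, 1, 0]
        a = mhg_statistic_and_pvalue(base)
        b = mhg_statistic_and_pvalue(base + [0, 0, 0])
        assert b.mhg_statistic <= a.mhg_statistic + 1e-15

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_pvalue_bounds(self, vec):
        if sum(vec) == 0:
            vec[0] = 1
        res = mhg_statistic_and_pvalue(vec)
        assert res.mhg_statistic - 1e-12 <= res.p_value
        assert res.p_value <= min(1.0, res.mhg_statistic * len(vec)) + 1e-12

    def test_sampling_fallback_agrees(self):
        vec = [1, 0, 1, 0, 0, 1, 0, 0, 0, 0]
        exact = mhg_statistic_and_pvalue(vec).p_value
        approx = mhg_pvalue_sampled(vec, n_permutations=4000, rng=0)
        assert approx == pytest.approx(exact, abs=0.04)

    def test_permutation_honest_under_relabeling(self, small_dataset):
        net = build_network(
            small_dataset.universe,
            enriched=list(small_dataset.ground_truth.hot_pathways),
        )
        _, vector = rank_by_degree(net)
        res1 = mhg_statistic_and_pvalue(vector)
        relabeled = nx.relabel_nodes(net.graph, {v: f"x_{v}" for v in net.graph})
        net2 = MetabolismNetwork(
            graph=relabeled,
            enriched=frozenset(f"x_{v}" for v in net.enriched),
        )
        _, vector2 = rank_by_degree(net2)
        res2 = mhg_statistic_and_pvalue(vector2)
        assert res1.p_value == pytest.approx(res2.p_value)


class TestDegreeComparison:
    def test_identical_multisets_equal_means(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        net = MetabolismNetwork(graph=g, enriched=frozenset(["a", "b"]))
        res = compare_degree_distributions(net)
        assert res["mean_enriched"] == res["mean_other"]

    def test_hand_enumerated_u_statistic(self):
        # degrees {4,5,6} vs {1,2,3}: every enriched beats every other
        g = nx.Graph()
        hubs = {"e1": 4, "e2": 5, "e3": 6, "o1": 1, "o2": 2, "o3": 3}
        for node, deg in hubs.items():
            for i in range(deg):
                g.add_edge(node, f"{node}_n{i}")
        # restrict comparison to the six labelled nodes via a subgraph test:
        from scipy import stats

        res = stats.mannwhitneyu([4, 5, 6], [1, 2, 3], alternative="two-sided")
        assert res.statistic == 9

    def test_planted_high_degree_enriched(self):
        g = nx.Graph()
        for i in range(3):  # enriched hubs touching everything
            for j in range(8):
                g.add_edge(f"hub{i}", f"leaf{j}")
        net = MetabolismNetwork(
            graph=g, enriched=frozenset(f"hub{i}" for i in range(3))
        )
        res = compare_degree_distributions(net)
        assert res["mean_enriched"] > res["mean_other"]

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_degree_distributions(star_network(enriched=()))


class TestDistanceShells:
    def test_path_graph_shells(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        shells = distance_shells(MetabolismNetwork(graph=g), ["A"])
        assert shells.shells == {1: {"B"}, 2: {"C"}}

    def test_merged_targets_count_node_once(self):
        g = nx.Graph([("t1", "x"), ("t2", "x")])
        shells = distance_shells(MetabolismNetwork(graph=g), ["t1", "t2"])
        assert shells.shells == {1: {"x"}}

    def test_max_mode_requires_reaching_every_target(self):
        g = nx.Graph([("t1", "x"), ("x", "t2"), ("t1", "y")])
        shells = distance_shells(MetabolismNetwork(graph=g), ["t1", "t2"], mode="max")
        assert shells.distances["x"] == 1
        assert shells.distances["y"] == 3  # y-t1=1 but y-t2=3

    def test_unreachable_nodes_reported_not_binned(self):
        g = nx.Graph([("A", "B")])
        g.add_node("island")
        shells = distance_shells(MetabolismNetwork(graph=g), ["A"])
        assert shells.unreachable == frozenset({"island"})
        assert "island" not in shells.distances

    def test_distances_match_floyd_warshall(self, small_dataset):
        net = build_network(small_dataset.universe)
        targets = sorted(net.graph.nodes)[:2]
        shells = distance_shells(net, targets)
        fw = nx.floyd_warshall(net.graph)
        for v in net.graph.nodes:
            d = min(fw[t][v] for t in targets)
            if v in targets:
                continue
            if d == float("inf"):
                assert v in shells.unreachable
            else:
                assert shells.distances[v] == int(d)

    def test_shells_partition_reachable_nodes(self, small_dataset):
        net = build_network(small_dataset.universe)
        targets = sorted(net.graph.nodes)[:2]
        shells = distance_shells(net, targets)
        total = sum(len(s) for s in shells.shells.values())
        assert total == len(shells.distances)
        assert total + len(shells.unreachable) + len(targets) == net.graph.number_of_nodes()


class TestShellEnrichment:
    def test_single_shell_degenerate_p_one(self):
        g = nx.Graph([("t", "a"), ("t", "b")])
        net = MetabolismNetwork(graph=g, enriched=frozenset(["a"]))
        shells = distance_shells(net, ["t"])
        res = shell_enrichment(shells, net.enriched)
        assert res[1]["p_value"] == pytest.approx(1.0)

    def test_concentrated_shell_attains_minimum_p(self):
        g = nx.Graph([("t", "a"), ("t", "b"), ("a", "c"), ("b", "d")])
        net = MetabolismNetwork(graph=g, enriched=frozenset(["a", "b"]))
        shells = distance_shells(net, ["t"])
        res = shell_enrichment(shells, net.enriched)
        # shell 1 holds both enriched of 4 assigned nodes: p = C(2,2)C(2,0)/C(4,2)
        assert res[1]["p_value"] == pytest.approx(1 / 6)

    def test_uniform_scatter_is_calibrated(self):
        """Permutation simulation: scattering enriched labels uniformly
        makes the shell-1 p-value stochastically near-uniform."""
        rng = np.random.default_rng(2)
        g = nx.random_geometric_graph(40, 0.3, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nodes = sorted(g.nodes)
        base = MetabolismNetwork(graph=g)
        shells = distance_shells(base, [nodes[0]])
        pvals = []
        assigned = sorted(shells.distances)
        for _ in range(200):
            enriched = rng.choice(assigned, size=8, replace=False)
            res = shell_enrichment(shells, set(enriched))
            pvals.append(res[1]["p_value"])
        assert 0.2 < np.mean(pvals) < 0.95  # discrete p-values are conservative


class TestDistanceComparison:
    def test_identical_multisets_t_zero(self):
        g = nx.path_graph(9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = MetabolismNetwork(graph=g)
        shells = distance_shells(net, ["n4"])
        # symmetric path: distances mirror around the target
        res = compare_distance_distributions(shells, {"n3", "n2", "n1", "n0"})
        assert res["t_statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_computed_welch_t(self):
        from scipy import stats

        res = stats.ttest_ind([1, 1, 2, 2], [3, 3, 4, 4], equal_var=False)
        assert res.statistic == pytest.approx(-4.898979485566356)

    def test_enriched_ringed_around_targets_are_closer(self):
        g = nx.Graph()
        for i in range(4):
            g.add_edge("t", f"ring{i}")
            g.add_edge(f"ring{i}", f"far{i}")
            g.add_edge(f"far{i}", f"farther{i}")
        net = MetabolismNetwork(
            graph=g, enriched=frozenset(f"ring{i}" for i in range(4))
        )
        shells = distance_shells(net, ["t"])
        res = compare_distance_distributions(shells, net.enriched)
        assert res["mean_enriched"] < res["mean_other"]

    def test_degenerate_group_sizes_raise(self):
        g = nx.Graph([("t", "a"), ("a", "b")])
        net = MetabolismNetwork(graph=g, enriched=frozenset(["a"]))
        shells = distance_shells(net, ["t"])
        with pytest.raises(ValueError):
            compare_distance_distributions(shells, net.enriched)


class TestExport:
    def test_graphml_counts(self, tmp_path):
        net = star_network(enriched=["hub"])
        path = tmp_path / "net.graphml"
        export_network(net, path, fmt="graphml")
        text = path.read_text()
        assert text.count("<node ") == 5 and text.count("<edge ") == 4

    @pytest.mark.parametrize("fmt", ["graphml", "edgelist"])
    def test_roundtrip(self, tmp_path, fmt, small_dataset):
        net = build_network(
            small_dataset.universe,
            enriched=list(small_dataset.ground_truth.hot_pathways),
        )
        path = tmp_path / f"net.{fmt}"
        export_network(net, path, fmt=fmt)
        back = import_network(path, fmt=fmt)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in net.graph.edges
        }
        assert back.enriched == net.enriched

    def test_empty_network_valid_document(self, tmp_path):
        net = MetabolismNetwork(graph=nx.Graph())
        export_network(net, tmp_path / "empty.graphml", fmt="graphml")
        back = import_network(tmp_path / "empty.graphml")
        assert back.graph.number_of_nodes() == 0

    def test_unknown_format_raises(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(star_network(), tmp_path / "x", fmt="dot")
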