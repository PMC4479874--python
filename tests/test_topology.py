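"""Degree statistics, hub taxonomy, clustering, MCL modules, participation."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccrn.topology import (
    DegreeDistribution,
    EdgeFilter,
    HubCategory,
    classify_hubs,
    clustering_coefficient,
    degree_distribution,
    fit_power_law,
    hub_associated_modules,
    hub_degree_cutoff,
    mcl_cluster,
    participation_coefficient,
)

from conftest import bicolor_network


def two_cliques_with_bridge(k=5):
    g = nx.Graph()
    for base in (0, k):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(base + i, base + j)
    g.add_edge(0, k)
    return g


class TestPowerLawFit:
    def test_exact_log_linear_input_recovered(self):
        pk = {k: 0.5 * k ** -1.5 for k in range(1, 21)}
        fit = fit_power_law(DegreeDistribution(degrees={}, pk=pk))
        assert fit.coefficient == pytest.approx(0.5, abs=1e-10)
        assert fit.exponent == pytest.approx(1.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_uniform_distribution_has_zero_exponent(self):
        pk = {k: 0.1 for k in range(1, 11)}
        fit = fit_power_law(DegreeDistribution(degrees={}, pk=pk))
        assert fit.exponent == pytest.approx(0.0, abs=1e-10)

    def test_multinomial_sample_recovers_exponent(self):
        rng = np.random.default_rng(123)
        ks = np.arange(1, 51)
        probs = ks ** -1.5
        probs /= probs.sum()
        counts = rng.multinomial(10_000, probs)
        pk = {int(k): c / 10_000 for k, c in zip(ks, counts) if c > 0}
        fit = fit_power_law(DegreeDistribution(degrees={}, pk=pk))
        assert fit.exponent == pytest.approx(1.5, abs=0.15)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError):
            fit_power_law(DegreeDistribution(degrees={}, pk={1: 0.5, 2: 0.5}))


class TestHubClassification:
    def test_competitive_fraction_categories(self):
        # hub H1: 8 of 10 edges competitive (0.8) -> competitive
        # hub H2: 5 of 10 edges competitive (0.5) -> modest
        edges = []
        for i in range(8):
            edges.append(("H1", f"a{i}", "competitive"))
        for i in range(2):
            edges.append(("H1", f"b{i}", "cooperative"))
        for i in range(5):
            edges.append(("H2", f"c{i}", "competitive"))
        for i in range(5):
            edges.append(("H2", f"d{i}", "cooperative"))
        net = bicolor_network(edges)
        hubs = {h.protein: h for h in classify_hubs(net, top_fraction=0.1)}
        assert hubs["H1"].category is HubCategory.COMPETITIVE
        assert hubs["H2"].category is HubCategory.MODEST

    def test_boundaries_are_inclusive_for_modest(self):
        edges = []
        for i in range(2):
            edges.append(("H", f"x{i}", "competitive"))
        for i in range(4):
            edges.append(("H", f"y{i}", "cooperative"))
        net = bicolor_network(edges)  # fraction exactly 1/3
        hub = next(h for h in classify_hubs(net, 0.1) if h.protein == "H")
        assert hub.category is HubCategory.MODEST

    def test_hub_set_matches_sort_and_threshold_oracle(self, rng):
        g = nx.gnm_random_graph(100, 400, seed=5)
        net = bicolor_network(
            [(f"n{u}", f"n{v}", "cooperative") for u, v in g.edges()]
        )
        hubs = {h.protein for h in classify_hubs(net, top_fraction=0.2)}
        degrees = dict(net.graph.degree())
        cutoff = sorted(degrees.values(), reverse=True)[math.ceil(0.2 * len(degrees)) - 1]
        oracle = {n for n, d in degrees.items() if d >= cutoff}
        assert hubs == oracle

    def test_every_higher_degree_node_is_a_hub(self):
        g = nx.barabasi_albert_graph(60, 2, seed=3)
        net = bicolor_network(
            [(f"n{u}", f"n{v}", "competitive") for u, v in g.edges()]
        )
        hubs = {h.protein for h in classify_hubs(net, 0.2)}
        cutoff = hub_degree_cutoff(net, 0.2)
        for node, degree in net.graph.degree():
            if degree > cutoff:
                assert node in hubs


class TestClusteringCoefficient:
    def test_triangle_node(self):
        net = bicolor_network(
            [("a", "b", "cooperative"), ("b", "c", "cooperative"), ("a", "c", "cooperative")]
        )
        assert clustering_coefficient(net, "a") == 1.0

    def test_star_center(self):
        net = bicolor_network([("h", f"p{i}", "cooperative") for i in range(4)])
        assert clustering_coefficient(net, "h") == 0.0

    def test_brute_force_neighbor_edge_count(self):
        # node with 4 neighbors linked by exactly 2 edges: 2*2/(4*3) = 1/3
        edges = [("x", f"n{i}", "cooperative") for i in range(4)]
        edges += [("n0", "n1", "cooperative"), ("n2", "n3", "cooperative")]
        net = bicolor_network(edges)
        assert clustering_coefficient(net, "x") == pytest.approx(1 / 3)

    def test_clique_and_tree_closed_forms(self):
        clique = bicolor_network(
            [(f"c{i}", f"c{j}", "competitive") for i in range(5) for j in range(i + 1, 5)]
        )
        for i in range(5):
            assert clustering_coefficient(clique, f"c{i}") == 1.0
        tree = bicolor_network(
            [("r", "a", "cooperative"), ("r", "b", "cooperative"), ("a", "c", "cooperative")]
        )
        for n in ["r", "a", "b", "c"]:
            assert clustering_coefficient(tree, n) == 0.0

    def test_color_restricted_filter(self):
        # x has 3 competitive neighbors forming 1 competitive edge among them,
        # plus cooperative neighbors that must be invisible under the filter
        edges = [("x", f"k{i}", "competitive") for i in range(3)]
        edges += [("k0", "k1", "competitive"), ("k1", "k2", "cooperative")]
        edges += [("x", f"q{i}", "cooperative") for i in range(3)]
        net = bicolor_network(edges)
        assert clustering_coefficient(net, "x", EdgeFilter.COMPETITIVE_ONLY) == pytest.approx(
            2 * 1 / (3 * 2)
        )

    def test_unknown_node_is_an_error(self):
        net = bicolor_network([("a", "b", "cooperative")])
        with pytest.raises(KeyError):
            clustering_coefficient(net, "zzz")


class TestMCL:
    def test_two_planted_cliques_recovered(self):
        partition = mcl_cluster(two_cliques_with_bridge(5), min_module_size=2)
        modules = {frozenset(m) for m in partition.modules}
        assert modules == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_single_clique_is_one_module(self):
        g = nx.complete_graph(6)
        partition = mcl_cluster(g)
        assert partition.n_modules == 1

    def test_modules_refine_connected_components(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2)])
        g.add_edges_from([(10, 11), (11, 12)])
        g.add_edges_from([(20, 21)])
        partition = mcl_cluster(g)
        components = list(nx.connected_components(g))
        for module in partition.modules:
            assert any(module <= comp for comp in components)

    def test_small_modules_flagged_not_retained(self):
        partition = mcl_cluster(two_cliques_with_bridge(5), min_module_size=4)
        assert all(keep for keep in partition.retained)
        partition2 = mcl_cluster(two_cliques_with_bridge(4), min_module_size=4)
        assert not any(partition2.retained)

    def test_non_positive_inflation_is_an_error(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.complete_graph(3), inflation=0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_partition_is_disjoint_and_covering(self, seed):
        g = nx.gnp_random_graph(18, 0.25, seed=seed)
        g.add_edge(0, 1)  # avoid the fully empty graph
        partition = mcl_cluster(g)
        seen = [n for m in partition.modules for n in m]
        assert len(seen) == len(set(seen)) == g.number_of_nodes()


class TestParticipationCoefficient:
    def _setup(self, k_per_module=3, n_modules=2):
        # node x links into n_modules cliques of retained size
        g = nx.Graph()
        modules = []
        for m in range(n_modules):
            members = [f"m{m}_{i}" for i in range(6)]
            for i in range(6):
                for j in range(i + 1, 6):
                    g.add_edge(members[i], members[j])
            modules.append(frozenset(members))
        return g, modules

    def test_all_links_within_own_module_is_zero(self):
        g, modules = self._setup()
        from ccrn.topology import ModulePartition

        partition = ModulePartition(modules=modules, retained=[True, True])
        p = participation_coefficient(g, partition, "m0_0")
        assert p == 0.0

    def test_even_split_across_two_modules(self):
        g, modules = self._setup()
        g.add_node("x")
        for t in ("m0_0", "m0_1", "m1_0", "m1_1"):
            g.add_edge("x", t)
        from ccrn.topology import ModulePartition

        partition = ModulePartition(
            modules=modules + [frozenset({"x", "y1", "y2", "y3", "y4", "y5"})],
            retained=[True, True, True],
        )
        assert participation_coefficient(g, partition, "x") == pytest.approx(0.5)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_equal_spread_over_m_modules(self, m):
        from ccrn.topology import ModulePartition

        g = nx.Graph()
        modules = []
        for s in range(m):
            members = [f"s{s}_{i}" for i in range(6)]
            g.add_edges_from((members[i], members[i + 1]) for i in range(5))
            modules.append(frozenset(members))
            g.add_edge("x", f"s{s}_0")
        modules.append(frozenset({"x", "z1", "z2", "z3", "z4", "z5"}))
        partition = ModulePartition(modules=modules, retained=[True] * (m + 1))
        assert participation_coefficient(g, partition, "x") == pytest.approx(1 - 1 / m)

    def test_neighbors_in_removed_modules_excluded(self):
        from ccrn.topology import ModulePartition

        g = nx.Graph()
        g.add_edges_from([("x", "a"), ("x", "b"), ("x", "tiny")])
        partition = ModulePartition(
            modules=[frozenset({"x", "a", "b", "c", "d", "e"}), frozenset({"tiny"})],
            retained=[True, False],
        )
        # neighbour 'tiny' drops out: both links stay in x's own module
        assert participation_coefficient(g, partition, "x") == 0.0

    def test_node_in_removed_module_is_undefined(self):
        from ccrn.topology import ModulePartition

        g = nx.Graph()
        g.add_edge("x", "a")
        partition = ModulePartition(
            modules=[frozenset({"x"}), frozenset({"a", "b", "c", "d", "e"})],
            retained=[False, True],
        )
        assert participation_coefficient(g, partition, "x") is None

    def test_absent_node_is_an_error(self):
        from ccrn.topology import ModulePartition

        g = nx.Graph()
        g.add_edge("x", "a")
        partition = ModulePartition(modules=[frozenset({"x", "a"})], retained=[True])
        with pytest.raises(KeyError):
            participation_coefficient(g, partition, "zzz")


class TestHubAssociatedModules:
    def _fixture(self):
        # competitive subgraph: two 5-cliques joined by a bridge, plus an
        # isolated competitive pair; the hub sits in the first clique
        g = two_cliques_with_bridge(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        g.add_edge("iso1", "iso2")
        from ccrn.topology import HubRecord

        hubs = [
            HubRecord(
                protein="n0", degree=10, competitive_fraction=0.9,
                category=HubCategory.COMPETITIVE, clustering_coefficient=1.0,
            )
        ]
        return g, hubs

    def test_intra_inter_and_unlabelled_pairs(self):
        g, hubs = self._fixture()
        partition, labels = hub_associated_modules(g, hubs, min_module_size=1)
        assert labels[("n0", "n1")] == "intra"  # inside the hub module
        assert labels[("n0", "n5")] == "inter"  # bridge to a non-hub module
        assert labels[("iso1", "iso2")] is None  # no hub anywhere near

    def test_no_competitive_hubs_is_an_error(self):
        g, _ = self._fixture()
        with pytest.raises(ValueError):
            hub_associated_modules(g, [])
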