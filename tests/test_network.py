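from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from topicnets import (
    AssociationSet,
    BipartiteNetwork,
    build_topic_network,
    degree_distribution_fit,
    enumerate_motifs,
    fit_power_law,
    global_properties,
    motif_significance,
    motif_zscore,
    randomize,
    simulate,
)

from conftest import make_model


def brute_force_motifs(net):
    """Independent oracle: classify every connected 3-node induced subgraph."""
    g = net.graph
    color = nx.get_node_attributes(g, "color")
    counts = {}
    for trio in combinations(g.nodes(), 3):
        sub = g.subgraph(trio)
        if not nx.is_connected(sub):
            continue
        n_edges = sub.number_of_edges()
        if n_edges == 3:
            label = "tri:" + "-".join(sorted(color[n][0].upper() for n in trio))
        else:
            center = next(n for n in trio if sub.degree(n) == 2)
            ends = sorted(color[n][0].upper() for n in trio if n != center)
            label = f"{ends[0]}-{color[center][0].upper()}-{ends[1]}"
        counts[label] = counts.get(label, 0) + 1
    return counts


def path_net():
    return BipartiteNetwork.from_edges([("D1", "G1"), ("D2", "G1")])


def star_net():
    return BipartiteNetwork.from_edges([(f"D{i}", "G1") for i in range(1, 5)])


class TestBipartiteNetwork:
    def test_same_color_edge_rejected(self):
        g = nx.Graph()
        g.add_node("a", color="disease")
        g.add_node("b", color="disease")
        g.add_edge("a", "b")
        with pytest.raises(ValueError, match="same-colored"):
            BipartiteNetwork(g)

    def test_duplicate_pairs_collapse(self):
        net = BipartiteNetwork.from_edges([("D1", "G1"), ("D1", "G1")])
        assert net.graph.number_of_edges() == 1

    def test_tsv_roundtrip(self, tmp_path):
        net = star_net()
        net.to_tsv(tmp_path / "e.tsv")
        back = BipartiteNetwork.from_tsv(tmp_path / "e.tsv")
        assert back.graph.number_of_edges() == 4
        assert len(back.diseases) == 4


class TestBuildTopicNetwork:
    def model(self):
        # topic 0: diseases d0, d1 and gene GA; topic 1: d2 / GB
        return make_model(
            n_ck=[[6.0, 0.0], [0.0, 2.0]],
            n_pk=[[3.0, 0.0], [3.0, 0.0], [0.0, 2.0]],
            vocabulary=["GA", "GB"], documents=["d0", "d1", "d2"],
        )

    def test_hand_assembly(self):
        assoc = AssociationSet({("d0", "GA"), ("d1", "GA")})
        net = build_topic_network(self.model(), 0, assoc)
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2

    def test_membership_filter_excludes_outside_gene(self):
        assoc = AssociationSet({("d0", "GA"), ("d0", "GB")})
        net = build_topic_network(self.model(), 0, assoc)
        assert net.graph.number_of_edges() == 1

    def test_duplicate_associations_single_edge(self):
        assoc = AssociationSet({("d0", "GA")})
        net = build_topic_network(self.model(), 0, assoc)
        assert net.graph.number_of_edges() == 1


class TestGlobalProperties:
    def test_path_diameter_and_cpl(self):
        props = global_properties(path_net())
        assert props["diameter"] == 2
        assert props["characteristic_path_length"] == pytest.approx(4 / 3)

    def test_star_hub_is_center(self):
        props = global_properties(star_net())
        assert props["diameter"] == 2
        assert [n for n in props["hubs"]] == [("G", "G1")]

    def test_disconnected_reports_largest_component(self):
        net = BipartiteNetwork.from_edges([("D1", "G1"), ("D2", "G2"), ("D3", "G2")])
        props = global_properties(net)
        assert not props["connected"]
        assert props["component_sizes"] == [3, 2]
        assert props["diameter"] == 2

    def test_cpl_bounded_by_diameter(self):
        for seed in range(5):
            net = simulate.generate_bipartite_network(12, 15, 40, "uniform", seed=seed)
            props = global_properties(net)
            assert props["characteristic_path_length"] <= props["diameter"]

    def test_double_star_diameter(self):
        # two stars joined through a shared gene: G1 to G2 crosses 4 edges
        edges = [("Da", "Gc"), ("Db", "Gc"), ("Da", "G1"), ("Db", "G2")]
        props = global_properties(BipartiteNetwork.from_edges(edges))
        assert props["diameter"] == 4


class TestDegreeDistribution:
    def test_exponent_recovery_from_exact_sample(self):
        # inverse-CDF sample from a discrete power law, gamma = 2.5
        rng = np.random.default_rng(0)
        gamma = 2.5
        ks = np.arange(1, 10_000)
        pmf = ks.astype(float) ** -gamma
        pmf /= pmf.sum()
        sample = rng.choice(ks, size=5000, p=pmf)
        fit = fit_power_law(sample)
        assert fit["heavy_tail"]
        assert fit["exponent"] == pytest.approx(2.5, abs=0.2)

    def test_preferential_network_in_plausible_range(self):
        net = simulate.generate_bipartite_network(
            1000, 1000, 4000, "preferential", seed=1
        )
        fit = degree_distribution_fit(net)
        assert fit["heavy_tail"]
        assert 1.5 <= fit["exponent"] <= 3.5

    def test_regular_graph_flagged(self):
        # perfect matching: every degree equals 1
        net = BipartiteNetwork.from_edges([(f"D{i}", f"G{i}") for i in range(12)])
        fit = degree_distribution_fit(net)
        assert not fit["heavy_tail"]


class TestEnumerateMotifs:
    def test_single_path(self):
        assert enumerate_motifs(path_net()) == {"D-G-D": 1}

    def test_star_binomial_count(self):
        assert enumerate_motifs(star_net()) == {"D-G-D": 6}

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nd, ng = rng.integers(3, 13), rng.integers(3, 13)
        n_edges = int(rng.integers(2, min(nd * ng, 30)))
        net = simulate.generate_bipartite_network(
            int(nd), int(ng), n_edges, "uniform", seed=seed
        )
        assert enumerate_motifs(net) == brute_force_motifs(net)

    def test_total_equals_connected_triples(self):
        net = simulate.generate_bipartite_network(8, 8, 20, "uniform", seed=3)
        assert sum(enumerate_motifs(net).values()) == sum(
            brute_force_motifs(net).values()
        )


class TestRandomize:
    def test_degree_sequence_and_colors_preserved(self):
        net = simulate.generate_bipartite_network(15, 20, 60, "preferential", seed=2)
        rnet = randomize(net, seed=5)
        assert dict(rnet.graph.degree()) == dict(net.graph.degree())
        assert rnet.diseases == net.diseases
        assert rnet.genes == net.genes
        assert rnet.graph.number_of_edges() == net.graph.number_of_edges()

    def test_two_edge_graph_reachable_states(self):
        net = BipartiteNetwork.from_edges([("D1", "G1"), ("D2", "G2")])
        seen = set()
        for seed in range(10):
            rnet = randomize(net, seed=seed, swaps_per_edge=1)
            seen.add(frozenset(rnet.graph.edges()))
        original = frozenset(net.graph.edges())
        crossed = frozenset({(("D", "D1"), ("G", "G2")), (("D", "D2"), ("G", "G1"))})
        normalized = {frozenset(frozenset(e) for e in s) for s in seen}
        assert normalized <= {
            frozenset(frozenset(e) for e in original),
            frozenset(frozenset(e) for e in crossed),
        }
        assert len(normalized) == 2  # the swap is exercised

    def test_seed_determinism(self):
        net = simulate.generate_bipartite_network(10, 10, 30, "uniform", seed=0)
        e1 = set(randomize(net, seed=9).graph.edges())
        e2 = set(randomize(net, seed=9).graph.edges())
        assert e1 == e2


class TestMotifSignificance:
    def test_zscore_formula(self):
        rand = [2, 4, 6]  # mean 4, population sd ~1.633
        z, p = motif_zscore(10, rand)
        assert z == pytest.approx((10 - 4) / np.std(rand))
        assert p == 0.0

    def test_zscore_hand_example(self):
        # N_real = 10 against a null with mean 4 and sd 2
        rand = [2, 2, 6, 6]
        z, _ = motif_zscore(10, rand)
        assert z == pytest.approx(3.0)

    def test_zero_spread_flagged(self):
        z, p = motif_zscore(5, [3, 3, 3])
        assert z is None
        assert p == 0.0

    def test_min_count_excludes_rare_patterns(self):
        net = path_net()  # single D-G-D occurrence
        results = motif_significance(net, n_random=10, min_count=5, seed=0)
        assert results == []

    def test_results_cover_frequent_patterns(self):
        net = simulate.generate_bipartite_network(10, 10, 35, "preferential", seed=4)
        results = motif_significance(net, n_random=50, min_count=5, seed=0)
        real = enumerate_motifs(net)
        expected = {p for p, c in real.items() if c >= 5}
        assert {r.pattern for r in results} == expected
        for r in results:
            assert 0.0 <= r.p <= 1.0
            assert r.n_random == 50
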