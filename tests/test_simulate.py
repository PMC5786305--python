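from itertools import permutations

import numpy as np
import pytest
from scipy.stats import pearsonr

from topicnets import AssociationSet, dgac, simulate


class TestGenerateCorpus:
    def test_seed_determinism(self):
        a = simulate.generate_corpus(K=4, P=30, C=40, seed=5)
        b = simulate.generate_corpus(K=4, P=30, C=40, seed=5)
        assert np.array_equal(a.corpus.counts, b.corpus.counts)
        assert np.array_equal(a.true_phi, b.true_phi)

    def test_single_topic_degenerate_mixture(self):
        planted = simulate.generate_corpus(K=1, P=10, C=20, seed=0)
        assert np.allclose(planted.true_theta, 1.0)

    def test_corpus_invariants_across_parameterizations(self):
        for K, P, C, ln, seed in [(2, 10, 15, 5, 0), (5, 40, 60, 30, 1), (3, 8, 3, 2, 2)]:
            planted = simulate.generate_corpus(K=K, P=P, C=C, mean_doc_len=ln, seed=seed)
            corp = planted.corpus
            assert (corp.counts.sum(axis=1) >= 1).all()
            assert (corp.counts.sum(axis=0) >= 1).all()
            assert np.allclose(planted.true_phi.sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(planted.true_theta.sum(axis=1), 1.0, atol=1e-9)

    def test_empirical_frequencies_track_mixture(self):
        planted = simulate.generate_corpus(
            K=5, P=200, C=100, alpha=0.1, beta=0.01, mean_doc_len=50, seed=1
        )
        corp = planted.corpus
        empirical = corp.counts.sum(axis=0) / corp.counts.sum()
        mass = planted.true_theta.mean(axis=0)  # mean topic usage
        expected = mass @ planted.true_phi
        r, _ = pearsonr(empirical, expected)
        assert r > 0.9

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate.generate_corpus(K=5, C=3, P=10)
        with pytest.raises(ValueError):
            simulate.generate_corpus(alpha=0.0)


class TestGenerateOntology:
    def test_complete_tree_term_count(self):
        dag, _ = simulate.generate_ontology(depth=3, branching=2, n_diseases=4, seed=0)
        assert len(dag.terms) == 1 + 2 + 4 + 8

    def test_depth_floor(self):
        with pytest.raises(ValueError):
            simulate.generate_ontology(depth=2, branching=2, n_diseases=4)

    def test_aligned_within_topic_rate_exceeds_between(self):
        from topicnets import diseases_similar

        planted = simulate.generate_corpus(K=3, P=30, C=40, seed=2)
        dag, ann = simulate.generate_ontology(
            depth=6, branching=3, n_diseases=30, aligned_topics=planted, seed=2
        )
        dominant = np.argmax(planted.true_theta, axis=1)
        docs = planted.corpus.documents
        within = between = within_n = between_n = 0
        for a in range(len(docs)):
            for b in range(a + 1, len(docs)):
                sim = diseases_similar(dag, docs[a], docs[b])
                if dominant[a] == dominant[b]:
                    within += bool(sim)
                    within_n += 1
                else:
                    between += bool(sim)
                    between_n += 1
        assert within / within_n > between / between_n

    def test_random_mode_rates_indistinguishable(self):
        from scipy.stats import chi2_contingency

        from topicnets import diseases_similar

        for seed in range(5):
            planted = simulate.generate_corpus(K=3, P=40, C=40, seed=seed)
            dag, ann = simulate.generate_ontology(
                depth=6, branching=3, n_diseases=40, seed=seed
            )
            dominant = np.argmax(planted.true_theta, axis=1)
            diseases = sorted(ann)
            table = np.zeros((2, 2))
            for a in range(len(diseases)):
                for b in range(a + 1, len(diseases)):
                    ja = planted.corpus.documents.index(diseases[a])
                    jb = planted.corpus.documents.index(diseases[b])
                    sim = bool(diseases_similar(dag, diseases[a], diseases[b]))
                    same = dominant[ja] == dominant[jb]
                    table[int(same), int(sim)] += 1
            if (table < 5).any():
                continue
            _, p, _, _ = chi2_contingency(table)
            assert p > 0.01


class TestGoldAssociations:
    def test_full_coverage_no_noise_is_subset_identity(self):
        planted = simulate.generate_corpus(K=3, P=20, C=30, seed=1)
        gold = simulate.generate_gold_associations(planted, coverage=1.0, noise=0.0)
        topic_assoc = AssociationSet(planted.corpus.association_set())
        assert dgac(topic_assoc, gold) == 1.0

    def test_half_coverage_tracks_binomial(self):
        planted = simulate.generate_corpus(K=3, P=50, C=60, mean_doc_len=30, seed=3)
        gold = simulate.generate_gold_associations(planted, coverage=0.5, noise=0.0, seed=4)
        topic_assoc = AssociationSet(planted.corpus.association_set())
        n = len(topic_assoc.pairs)
        observed = dgac(topic_assoc, gold)
        assert abs(observed - 0.5) < 3 * np.sqrt(0.25 / n) + 1 / n

    def test_noise_only_pairs_never_generated(self):
        planted = simulate.generate_corpus(K=3, P=20, C=30, seed=5)
        gold = simulate.generate_gold_associations(planted, coverage=1.0, noise=0.3, seed=6)
        true_pairs = planted.corpus.association_set()
        noise_pairs = gold.pairs - true_pairs
        assert noise_pairs
        assert dgac(AssociationSet(noise_pairs), AssociationSet(true_pairs)) == 0.0


class TestGenerateBipartiteNetwork:
    def test_uniform_saturation_complete(self):
        net = simulate.generate_bipartite_network(4, 5, 20, "uniform", seed=0)
        assert net.graph.number_of_edges() == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_preferential_heavy_tail(self, seed):
        net = simulate.generate_bipartite_network(1000, 1000, 4000, "preferential", seed=seed)
        degrees = np.array([d for _, d in net.graph.degree()])
        assert degrees.max() > 5 * np.median(degrees)

    def test_seed_determinism(self):
        e1 = set(simulate.generate_bipartite_network(10, 10, 30, seed=7).graph.edges())
        e2 = set(simulate.generate_bipartite_network(10, 10, 30, seed=7).graph.edges())
        assert e1 == e2

    def test_edge_budget_validated(self):
        with pytest.raises(ValueError):
            simulate.generate_bipartite_network(3, 3, 10, "uniform")


class TestMatchTopics:
    def test_recovers_planted_permutation(self):
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.full(30, 0.05), size=4)
        perm = np.array([2, 0, 3, 1])
        learned = phi[perm]
        recovered, cos = simulate.match_topics(phi, learned)
        assert cos == pytest.approx(1.0)
        # learned topic recovered[k] corresponds to true topic k
        assert np.allclose(learned[recovered], phi)

    def test_uniform_rows_closed_form(self):
        phi = np.eye(3)
        uniform = np.full((3, 3), 1 / 3)
        _, cos = simulate.match_topics(phi, uniform)
        assert cos == pytest.approx(1 / np.sqrt(3))

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(3)
        true_phi = rng.dirichlet(np.ones(8), size=3)
        learned = rng.dirichlet(np.ones(8), size=3)
        _, cos = simulate.match_topics(true_phi, learned)

        def cosine(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        brute = max(
            np.mean([cosine(true_phi[k], learned[p[k]]) for k in range(3)])
            for p in permutations(range(3))
        )
        assert cos == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            simulate.match_topics(np.ones((2, 3)), np.ones((3, 3)))
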