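"""Synthetic data with known ground truth for every pipeline stage.

The corpus generator follows the model's own generative process: per-topic
gene distributions drawn from Dirichlet(beta), per-disease topic mixtures
from Dirichlet(alpha), document lengths Poisson (truncated at one token),
tokens by topic-then-gene multinomial draws. Companion generators produce a
rooted disease-ontology tree with (optionally topic-aligned) annotations,
gold-standard association sets at controlled coverage and noise, and
bipartite networks with uniform or preferential (heavy-tailed) attachment.
All generators are deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)
from scipy.optimize import linear_sum_assignment

from .corpus import Corpus
from .metrics import AssociationSet
from .network import BipartiteNetwork
from .ontology import OntologyDAG


@dataclass
class PlantedCorpus:
    """A synthetic corpus bundled with its generating parameters."""

    corpus: Corpus
    true_phi: np.ndarray
    true_theta: np.ndarray
    params: dict

    @property
    def n_topics(self) -> int:
        return self.true_phi.shape[0]


def generate_corpus(
    K: int = 10,
    P: int = 300,
    C: int = 200,
    alpha: float = 0.1,
    beta: float = 0.01,
    mean_doc_len: float = 50.0,
    seed: int = 0,
) -> PlantedCorpus:
    """Draw a Dirichlet-multinomial corpus with planted topics.

    Documents that end up with an empty row (possible only if a length-0
    draw slipped through truncation) cannot occur: lengths are Poisson
    truncated at 1. Vocabulary entries never drawn are kept out of the
    corpus, with ``true_phi`` restricted accordingly.
    """
    if min(K, P, C) < 1 or alpha <= 0 or beta <= 0 or mean_doc_len <= 0:
        raise ValueError("all generator parameters must be positive")
    if C < K:
        raise ValueError("need C >= K")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(C, beta), size=K)
    theta = rng.dirichlet(np.full(K, alpha), size=P)
    lengths = np.maximum(rng.poisson(mean_doc_len, size=P), 1)
    counts = np.zeros((P, C), dtype=np.int64)
    for j in range(P):
        z = rng.choice(K, size=lengths[j], p=theta[j])
        for k in np.unique(z):
            n_k = int(np.sum(z == k))
            counts[j] += rng.multinomial(n_k, phi[k])
    used = counts.sum(axis=0) >= 1
    corpus = Corpus(
        documents=[f"d{j:04d}" for j in range(P)],
        vocabulary=[f"G{i:04d}" for i in range(C) if used[i]],
        counts=counts[:, used],
    )
    phi_used = phi[:, used]
    phi_used = phi_used / phi_used.sum(axis=1, keepdims=True)
    return PlantedCorpus(
        corpus=corpus,
        true_phi=phi_used,
        true_theta=theta,
        params={"K": K, "P": P, "C": C, "alpha": alpha, "beta": beta,
                "mean_doc_len": mean_doc_len, "seed": seed},
    )


def generate_ontology(
    depth: int = 3,
    branching: int = 2,
    n_diseases: int = 20,
    aligned_topics: PlantedCorpus | None = None,
    seed: int = 0,
) -> tuple[OntologyDAG, dict[str, set[str]]]:
    """A complete rooted tree ontology with disease annotations.

    When ``aligned_topics`` is given, each planted topic is anchored at a
    distinct node three levels above the leaves and its dominant diseases
    are annotated to leaves below that anchor — any two same-topic diseases
    then share the anchor as a common ancestor within three levels, while
    cross-topic pairs do not (for depth > 3). Otherwise annotations are
    uniform over leaves.
    """
    if depth < 3:
        raise ValueError("depth must be >= 3")
    rng = np.random.default_rng(seed)
    terms = {"t0"}
    parents: dict[str, set[str]] = {}
    levels: list[list[str]] = [["t0"]]
    counter = 1
    for _ in range(depth):
        prev, cur = levels[-1], []
        for parent in prev:
            for _ in range(branching):
                term = f"t{counter}"
                counter += 1
                terms.add(term)
                parents[term] = {parent}
                cur.append(term)
        levels.append(cur)
    leaves = levels[-1]

    if aligned_topics is not None:
        theta = aligned_topics.true_theta
        docs = aligned_topics.corpus.documents
        anchor_level = max(0, depth - 3)
        anchors = levels[anchor_level]
        # leaves grouped under each anchor-level node
        anchor_leaves: dict[str, list[str]] = {a: [] for a in anchors}
        for leaf in leaves:
            node = leaf
            for _ in range(depth - anchor_level):
                node = next(iter(parents[node]))
            anchor_leaves[node].append(leaf)
        K = aligned_topics.n_topics
        if K > len(anchors):
            logger.warning("more topics than anchor nodes: anchors reused")
        topic_anchor = [anchors[int(k * len(anchors) / K) % len(anchors)] for k in range(K)]
        diseases = docs[:n_diseases] if n_diseases <= len(docs) else docs
        annotations = {}
        for j, d in enumerate(diseases):
            pool = anchor_leaves[topic_anchor[int(np.argmax(theta[j]))]]
            annotations[d] = {pool[rng.integers(len(pool))]}
    else:
        diseases = [f"d{j:04d}" for j in range(n_diseases)]
        annotations = {d: {leaves[rng.integers(len(leaves))]} for d in diseases}
    dag = OntologyDAG(terms=terms, parents=parents, annotations=annotations)
    return dag, annotations


def generate_gold_associations(
    planted: PlantedCorpus,
    coverage: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> AssociationSet:
    """Sample an OMIM-style gold standard from the planted corpus.

    Keeps a ``coverage`` fraction of the true disease-gene pairs (pairs the
    generator actually emitted) and adds ``noise`` (relative to the kept
    count) never-generated pairs drawn uniformly from the complement.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true_pairs = sorted(planted.corpus.association_set())
    n_keep = max(1, round(coverage * len(true_pairs)))
    keep_idx = rng.choice(len(true_pairs), size=n_keep, replace=False)
    kept = {true_pairs[i] for i in keep_idx}
    n_noise = round(noise * n_keep)
    if n_noise:
        docs, vocab = planted.corpus.documents, planted.corpus.vocabulary
        true_set = set(true_pairs)
        added = 0
        while added < n_noise:
            pair = (docs[rng.integers(len(docs))], vocab[rng.integers(len(vocab))])
            if pair not in true_set and pair not in kept:
                kept.add(pair)
                added += 1
    return AssociationSet(pairs=kept)


def generate_bipartite_network(
    n_disease: int = 50,
    n_gene: int = 80,
    edges: int = 200,
    attachment: str = "preferential",
    seed: int = 0,
) -> BipartiteNetwork:
    """A random simple bipartite disease-gene network.

    ``preferential`` grows the network one node at a time (shuffled disease
    and gene arrivals), attaching each new node's edges to existing
    opposite-side nodes with probability proportional to degree plus one —
    the bipartite analogue of preferential-attachment growth, yielding
    heavy-tailed degrees. ``uniform`` samples disease-gene pairs without
    replacement.
    """
    if edges > n_disease * n_gene:
        raise ValueError("more edges than disease-gene pairs")
    rng = np.random.default_rng(seed)
    diseases = [f"d{j:03d}" for j in range(n_disease)]
    genes = [f"G{i:03d}" for i in range(n_gene)]
    pairs: set[tuple[int, int]] = set()
    if attachment == "uniform":
        flat = rng.choice(n_disease * n_gene, size=edges, replace=False)
        pairs = {(int(f) // n_gene, int(f) % n_gene) for f in flat}
    elif attachment == "preferential":
        arrivals = [("d", j) for j in range(1, n_disease)] + [("g", i) for i in range(1, n_gene)]
        rng.shuffle(arrivals)
        d_deg = np.zeros(n_disease)
        g_deg = np.zeros(n_gene)
        present_d, present_g = [0], [0]
        pairs.add((0, 0))
        d_deg[0] = g_deg[0] = 1
        quota = np.full(len(arrivals), (edges - 1) // len(arrivals))
        quota[: (edges - 1) % len(arrivals)] += 1
        for (side, idx), m in zip(arrivals, quota):
            targets = present_g if side == "d" else present_d
            deg = g_deg if side == "d" else d_deg
            for _ in range(max(int(m), 1) if m else 0):
                w = deg[targets] + 1.0
                for _attempt in range(20):
                    t = targets[rng.choice(len(targets), p=w / w.sum())]
                    pair = (idx, t) if side == "d" else (t, idx)
                    if pair not in pairs:
                        break
                else:
                    continue
                pairs.add(pair)
                d_deg[pair[0]] += 1
                g_deg[pair[1]] += 1
            (present_d if side == "d" else present_g).append(idx)
        # top up any shortfall with preferential draws on both sides
        while len(pairs) < edges:
            d = rng.choice(n_disease, p=(d_deg + 1) / (d_deg + 1).sum())
            g = rng.choice(n_gene, p=(g_deg + 1) / (g_deg + 1).sum())
            if (int(d), int(g)) in pairs:
                continue
            pairs.add((int(d), int(g)))
            d_deg[d] += 1
            g_deg[g] += 1
    else:
        raise ValueError("attachment must be 'preferential' or 'uniform'")
    return BipartiteNetwork.from_edges(
        [(diseases[d], genes[g]) for d, g in sorted(pairs)],
        diseases=diseases, genes=genes,
    )


def match_topics(true_phi: np.ndarray, learned_phi: np.ndarray) -> tuple[np.ndarray, float]:
    """Hungarian matching of learned to planted topics by row cosine.

    Returns the permutation pi (learned topic pi[k] matches true topic k)
    and the mean matched cosine similarity.
    """
    true_phi = np.asarray(true_phi, dtype=float)
    learned_phi = np.asarray(learned_phi, dtype=float)
    if true_phi.shape != learned_phi.shape:
        raise ValueError("true and learned phi must have identical shape")
    tn = true_phi / np.linalg.norm(true_phi, axis=1, keepdims=True)
    ln = learned_phi / np.linalg.norm(learned_phi, axis=1, keepdims=True)
    sim = tn @ ln.T
    rows, cols = linear_sum_assignment(-sim)
    return cols, float(sim[rows, cols].mean())
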