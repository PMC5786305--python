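"""Similarity and coverage statistics over fitted disease topics.

Three statistics summarize topic structure: a symmetric Kullback-Leibler
divergence between two genes' topic-conditional probability vectors
(``KL(p||q) + KL(q||p)``, natural log), the cosine similarity between
topics' gene or disease vectors, and the disease-gene association coverage
``|A ∩ B| / |A|`` of a topic's association set A against a gold standard B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lda import LatentTopicModel


@dataclass
class TopicVector:
    """Labelled non-negative weight vector for a topic's genes or diseases."""

    ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.ids) != len(self.weights):
            raise ValueError("ids and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


@dataclass
class AssociationSet:
    """Set of unique (disease id, gene id) pairs."""

    pairs: set[tuple[str, str]]

    @classmethod
    def from_tsv(cls, path) -> "AssociationSet":
        pairs = set()
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            d, g = line.split("\t")[:2]
            pairs.add((d, g))
        return cls(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for d, g in sorted(self.pairs):
                fh.write(f"{d}\t{g}\n")


def ldakl(p, q, eps: float = 1e-12) -> float:
    """Symmetric KL divergence KL(p||q) + KL(q||p), natural log.

    Inputs must be probability vectors of equal length; add-eps smoothing
    followed by renormalization guards exact zeros (a no-op on
    Dirichlet-smoothed posteriors, which are strictly positive).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()})")
    p = (p + eps) / (p + eps).sum()
    q = (q + eps) / (q + eps).sum()
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def gene_topic_distribution(
    model: LatentTopicModel, gene: str, conditioning: str = "gene_given_topic"
) -> np.ndarray:
    """A gene's probability vector over topics, for :func:`ldakl`.

    ``gene_given_topic`` normalizes the vector of per-topic probabilities
    p(c|t) (the topic-gene posterior column); ``topic_given_gene`` weights
    each p(c|t) by the topic's mass before normalizing, giving the posterior
    p(t|c).
    """
    i = model.vocabulary_.index(gene)
    col = model.phi_hat_[:, i].astype(float)
    if conditioning == "topic_given_gene":
        col = col * model.n_ck_.sum(axis=1)
    elif conditioning != "gene_given_topic":
        raise ValueError("conditioning must be 'gene_given_topic' or 'topic_given_gene'")
    return col / col.sum()


def cosine_similarity(x, y) -> float:
    """Cosine similarity of two aligned non-negative vectors, in [0, 1]."""
    if isinstance(x, TopicVector) and isinstance(y, TopicVector):
        if x.ids != y.ids:
            raise ValueError("TopicVector ids must be aligned")
        x, y = x.weights, y.weights
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0:
        raise ValueError("zero vector: x")
    if ny == 0:
        raise ValueError("zero vector: y")
    return float(np.dot(x, y) / (nx * ny))


def topic_similarity_matrix(
    model: LatentTopicModel, level: str = "gene", binary: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise topic cosine similarities plus a ten-bin histogram on [0, 1].

    ``gene`` level compares topic-gene posterior rows; ``disease`` level
    compares each topic's normalized mass over diseases (document-topic count
    columns). ``binary`` thresholds vectors to membership indicators first.
    The histogram counts unordered off-diagonal pairs in ten equal intervals
    partitioning [0, 1].

    Returns (matrix, histogram counts, bin edges).
    """
    if level == "gene":
        vectors = model.phi_hat_.copy()
    elif level == "disease":
        cols = model.n_pk_.T.astype(float)  # (K, P)
        sums = cols.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        vectors = cols / sums
    else:
        raise ValueError("level must be 'gene' or 'disease'")
    if binary:
        vectors = (vectors > 1e-6).astype(float)
    K = vectors.shape[0]
    sim = np.eye(K)
    for a in range(K):
        for b in range(a + 1, K):
            sim[a, b] = sim[b, a] = cosine_similarity(vectors[a], vectors[b])
    edges = np.linspace(0.0, 1.0, 11)
    off = sim[np.triu_indices(K, k=1)]
    hist, _ = np.histogram(np.clip(off, 0.0, 1.0), bins=edges)
    return sim, hist, edges


def dgac(a: AssociationSet, b: AssociationSet) -> float:
    """Disease-gene association coverage |A ∩ B| / |A| in [0, 1]."""
    if not a.pairs:
        raise ValueError("association set A must be non-empty")
    return len(a.pairs & b.pairs) / len(a.pairs)


def top_entities(
    model: LatentTopicModel, topic: int, n: int, level: str = "gene"
) -> list[tuple[str, float]]:
    """Top-n genes or diseases of a topic by probability (lexicographic ties)."""
    if not 0 <= topic < model.n_topics:
        raise IndexError(f"topic index {topic} out of range")
    if n < 1:
        raise ValueError("n must be >= 1")
    if level == "gene":
        ids, probs = model.vocabulary_, model.phi_hat_[topic]
    elif level == "disease":
        ids, probs = model.documents_, model.theta_hat_[:, topic]
    else:
        raise ValueError("level must be 'gene' or 'disease'")
    ranked = sorted(zip(ids, probs), key=lambda t: (-t[1], t[0]))
    return [(i, float(p)) for i, p in ranked[:n]]
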