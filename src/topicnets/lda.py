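"""Latent Dirichlet allocation over disease-as-document corpora.

The generative model: each disease (document) ``p_j`` draws a topic mixture
``theta_j ~ Dirichlet(alpha)``; each topic ``k`` draws a gene distribution
``phi_k ~ Dirichlet(beta)``; each gene token first draws a topic from
``theta_j`` and then a gene from ``phi_k``. Inference is collapsed: the
default is the zeroth-order collapsed variational update (CVB0), which is
deterministic given its seeded initialization; collapsed Gibbs sampling is
available as a stochastic cross-check.

Posterior point estimates are the Dirichlet-smoothed expected counts

    phi_hat[k, i]  = (n_ck[k, i] + beta)  / (sum_i n_ck[k, i] + C * beta)
    theta_hat[j, k] = (n_pk[j, k] + alpha) / (sum_k n_pk[j, k] + K * alpha)

and model comparison uses the collapsed log evidence of the gene tokens
given their topic assignments,

    log p(c | z) = T * [lnG(C*beta) - C * lnG(beta)]
                 + sum_t [ sum_i lnG(n_t_i + beta) - lnG(n_t + C*beta) ]

with lnG the log-gamma function; the topic number is chosen by maximizing
this score over a grid (the Griffiths-Steyvers heuristic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .corpus import Corpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperparameters:
    """Dirichlet concentrations and topic count for the LDA model."""

    alpha: float = 0.1
    beta: float = 0.01
    n_topics: int = 10

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.n_topics < 2:
            raise ValueError("n_topics must be at least 2")


@dataclass
class FitTrace:
    """Per-iteration log-likelihood trace of one fit."""

    iterations: list[int] = field(default_factory=list)
    log_likelihood: list[float] = field(default_factory=list)
    converged: bool = False
    seed: int = 0

    def record(self, iteration: int, ll: float) -> None:
        self.iterations.append(iteration)
        self.log_likelihood.append(float(ll))


def estimate_phi(n_ck: np.ndarray, beta: float) -> np.ndarray:
    """Topic-gene posterior point estimate (row-stochastic, K x C)."""
    n_ck = np.asarray(n_ck, dtype=float)
    if np.any(n_ck < 0):
        raise ValueError("n_ck must be non-negative")
    C = n_ck.shape[1]
    return (n_ck + beta) / (n_ck.sum(axis=1, keepdims=True) + C * beta)


def estimate_theta(n_pk: np.ndarray, alpha: float) -> np.ndarray:
    """Document-topic posterior point estimate (row-stochastic, P x K)."""
    n_pk = np.asarray(n_pk, dtype=float)
    if np.any(n_pk < 0):
        raise ValueError("n_pk must be non-negative")
    K = n_pk.shape[1]
    return (n_pk + alpha) / (n_pk.sum(axis=1, keepdims=True) + K * alpha)


def _collapsed_log_evidence(n_ck: np.ndarray, beta: float) -> float:
    """log p(c|z) from topic-gene counts (expected counts allowed)."""
    n_ck = np.asarray(n_ck, dtype=float)
    K, C = n_ck.shape
    n_k = n_ck.sum(axis=1)
    const = K * (gammaln(C * beta) - C * gammaln(beta))
    return float(const + gammaln(n_ck + beta).sum() - gammaln(n_k + C * beta).sum())


def _collapsed_assignment_prior(n_pk: np.ndarray, alpha: float) -> float:
    """log p(z|alpha) from document-topic counts (expected counts allowed)."""
    n_pk = np.asarray(n_pk, dtype=float)
    P, K = n_pk.shape
    const = P * (gammaln(K * alpha) - K * gammaln(alpha))
    return float(
        const + gammaln(n_pk + alpha).sum() - gammaln(n_pk.sum(axis=1) + K * alpha).sum()
    )


def _as_counts(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, Corpus):
        return X.counts, X.documents, X.vocabulary
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a document-by-gene count matrix")
    return X, None, None


class LatentTopicModel(BaseEstimator):
    """LDA with collapsed variational (CVB0) or collapsed Gibbs inference.

    Parameters
    ----------
    n_topics : int
        Number of latent topics K (>= 2).
    alpha, beta : float
        Symmetric Dirichlet concentrations for document-topic and topic-gene
        distributions. Defaults 0.1 and 0.01.
    iterations : int
        Sweeps over the corpus.
    seed : int
        Controls initialization (and, for Gibbs, the sampling path); fits are
        exactly reproducible per seed.
    algorithm : {"cvb0", "gibbs"}
    eval_every : int
        Record the log-likelihood trace every this many iterations.
    tol, patience : float, int
        Optional early stop: relative log-likelihood change below ``tol`` for
        ``patience`` consecutive recorded evaluations. ``tol=0`` disables.

    Attributes
    ----------
    phi_hat_ : ndarray (K, C)
        Row-stochastic topic-gene posterior estimate.
    theta_hat_ : ndarray (P, K)
        Row-stochastic document-topic posterior estimate.
    n_ck_, n_pk_ : ndarray
        Expected (CVB0) or sampled (Gibbs) topic-gene / document-topic counts.
    responsibilities_ : ndarray (n_pairs, K)
        Per unique document-gene pair topic responsibilities.
    trace_ : FitTrace
    """

    def __init__(
        self,
        n_topics: int = 10,
        alpha: float = 0.1,
        beta: float = 0.01,
        iterations: int = 1000,
        seed: int = 0,
        algorithm: str = "cvb0",
        eval_every: int = 10,
        tol: float = 1e-4,
        patience: int = 10,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.iterations = iterations
        self.seed = seed
        self.algorithm = algorithm
        self.eval_every = eval_every
        self.tol = tol
        self.patience = patience

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None) -> "LatentTopicModel":
        """Fit on a :class:`~topicnets.corpus.Corpus` or (P, C) count matrix."""
        Hyperparameters(self.alpha, self.beta, self.n_topics)  # validate
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.algorithm not in ("cvb0", "gibbs"):
            raise ValueError("algorithm must be 'cvb0' or 'gibbs'")
        counts, docs, vocab = _as_counts(X)
        if counts.sum() < 1:
            raise ValueError("cannot fit an empty corpus")
        self.documents_ = docs if docs is not None else [str(j) for j in range(counts.shape[0])]
        self.vocabulary_ = vocab if vocab is not None else [str(i) for i in range(counts.shape[1])]

        if self.algorithm == "cvb0":
            self._fit_cvb0(counts)
        else:
            self._fit_gibbs(counts)
        self.phi_hat_ = estimate_phi(self.n_ck_, self.beta)
        self.theta_hat_ = estimate_theta(self.n_pk_, self.alpha)
        self.components_ = self.phi_hat_
        return self

    def _fit_cvb0(self, counts: np.ndarray) -> None:
        K = self.n_topics
        P, C = counts.shape
        rng = np.random.default_rng(self.seed)
        d_idx, w_idx = np.nonzero(counts)
        cnt = counts[d_idx, w_idx].astype(float)

        # uniform-Dirichlet initial responsibilities per unique (doc, gene) pair
        R = rng.dirichlet(np.ones(K), size=len(d_idx))
        trace = FitTrace(seed=self.seed)
        flat = np.zeros(0)
        stall = 0
        for it in range(1, self.iterations + 1):
            n_ck = np.zeros((K, C))
            np.add.at(n_ck.T, (w_idx,), cnt[:, None] * R)
            n_pk = np.zeros((P, K))
            np.add.at(n_pk, (d_idx,), cnt[:, None] * R)
            n_k = n_ck.sum(axis=1)

            # exclude one token's own mass (grouped CVB0)
            A = n_ck[:, w_idx].T - R
            B = n_pk[d_idx, :] - R
            N = n_k[None, :] - R
            np.clip(A, 0.0, None, out=A)
            np.clip(B, 0.0, None, out=B)
            np.clip(N, 0.0, None, out=N)
            R = (A + self.beta) * (B + self.alpha) / (N + C * self.beta)
            norm = R.sum(axis=1, keepdims=True)
            if not np.all(np.isfinite(R)) or np.any(norm <= 0):
                raise FloatingPointError(f"non-finite responsibilities at iteration {it}")
            R /= norm

            if it % self.eval_every == 0 or it == self.iterations:
                n_ck = np.zeros((K, C))
                np.add.at(n_ck.T, (w_idx,), cnt[:, None] * R)
                ll = _collapsed_log_evidence(n_ck, self.beta)
                trace.record(it, ll)
                if self.tol > 0 and len(trace.log_likelihood) >= 2:
                    prev = trace.log_likelihood[-2]
                    if abs(ll - prev) < self.tol * abs(ll):
                        stall += 1
                    else:
                        stall = 0
                    if stall >= self.patience:
                        trace.converged = True
                        break

        n_ck = np.zeros((K, C))
        np.add.at(n_ck.T, (w_idx,), cnt[:, None] * R)
        n_pk = np.zeros((P, K))
        np.add.at(n_pk, (d_idx,), cnt[:, None] * R)
        self.n_ck_, self.n_pk_ = n_ck, n_pk
        self.responsibilities_ = R
        self._pair_index_ = (d_idx, w_idx, cnt)
        if not trace.iterations:
            trace.record(self.iterations, _collapsed_log_evidence(n_ck, self.beta))
        self.trace_ = trace

    def _fit_gibbs(self, counts: np.ndarray) -> None:
        K = self.n_topics
        P, C = counts.shape
        rng = np.random.default_rng(self.seed)
        d_idx, w_idx = np.nonzero(counts)
        cnt = counts[d_idx, w_idx]
        doc = np.repeat(d_idx, cnt)
        word = np.repeat(w_idx, cnt)
        n_tok = len(doc)

        z = rng.integers(0, K, size=n_tok)
        n_ck = np.zeros((K, C))
        n_pk = np.zeros((P, K))
        np.add.at(n_ck, (z, word), 1)
        np.add.at(n_pk, (doc, z), 1)
        n_k = n_ck.sum(axis=1)

        trace = FitTrace(seed=self.seed)
        Cb = C * self.beta
        for it in range(1, self.iterations + 1):
            for t in range(n_tok):
                d, w, k_old = doc[t], word[t], z[t]
                n_ck[k_old, w] -= 1
                n_pk[d, k_old] -= 1
                n_k[k_old] -= 1
                p = (n_ck[:, w] + self.beta) * (n_pk[d] + self.alpha) / (n_k + Cb)
                k_new = rng.choice(K, p=p / p.sum())
                z[t] = k_new
                n_ck[k_new, w] += 1
                n_pk[d, k_new] += 1
                n_k[k_new] += 1
            if it % self.eval_every == 0 or it == self.iterations:
                trace.record(it, _collapsed_log_evidence(n_ck, self.beta))
        self.n_ck_, self.n_pk_ = n_ck, n_pk
        # hard assignments as one-hot responsibilities per token group
        self.responsibilities_ = None
        self.assignments_ = z
        self._pair_index_ = (d_idx, w_idx, cnt)
        self.trace_ = trace

    # -- inference on fitted model ---------------------------------------

    def transform(self, X) -> np.ndarray:
        """Fold in new documents: document-topic estimates under fixed topics."""
        counts, _, _ = _as_counts(X)
        phi = self.phi_hat_
        K = self.n_topics
        theta = np.full((counts.shape[0], K), 1.0 / K)
        for _ in range(50):
            # EM over token-topic responsibilities with phi fixed
            r = theta[:, :, None] * phi[None, :, :]  # (P, K, C)
            r /= r.sum(axis=1, keepdims=True)
            n_pk = (r * counts[:, None, :]).sum(axis=2)
            theta = estimate_theta(n_pk, self.alpha)
        return theta

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).theta_hat_

    def score(self, X=None, y=None) -> float:
        """Collapsed log evidence of the fitted assignments."""
        return log_likelihood(self)


def log_likelihood(model: LatentTopicModel, corpus: Corpus | None = None) -> float:
    """Collapsed log evidence log p(c|z) of a fitted model's counts."""
    return _collapsed_log_evidence(model.n_ck_, model.beta)


def fit(
    corpus: Corpus,
    hyper: Hyperparameters | None = None,
    iterations: int = 1000,
    seed: int = 0,
    algorithm: str = "cvb0",
    **kwargs,
) -> tuple[LatentTopicModel, FitTrace]:
    """Functional wrapper over :class:`LatentTopicModel`."""
    hyper = hyper or Hyperparameters()
    model = LatentTopicModel(
        n_topics=hyper.n_topics,
        alpha=hyper.alpha,
        beta=hyper.beta,
        iterations=iterations,
        seed=seed,
        algorithm=algorithm,
        **kwargs,
    ).fit(corpus)
    return model, model.trace_


def select_topic_number(
    corpus: Corpus,
    k_grid,
    iterations: int = 200,
    seeds=(0, 1, 2),
    alpha: float = 0.1,
    beta: float = 0.01,
    algorithm: str = "cvb0",
    score: str = "joint",
) -> tuple[int, dict[int, float]]:
    """Choose the topic number maximizing the mean collapsed log-likelihood.

    Fits the model at every K in ``k_grid`` for every seed and returns the
    grid value with the highest mean score (smallest K on ties, reported via
    log) together with the per-K score table.

    The default ``score="joint"`` ranks by the complete collapsed evidence
    log p(c, z) = log p(c|z) + log p(z|alpha): the assignment-prior term is
    where the Occam penalty against surplus topics lives, so the joint score
    peaks at the planted topic number where the token term log p(c|z) alone
    keeps improving with K at a converged variational optimum.
    ``score="tokens"`` ranks by log p(c|z) only.
    """
    if score not in ("joint", "tokens"):
        raise ValueError("score must be 'joint' or 'tokens'")
    k_grid = sorted(int(k) for k in k_grid)
    if len(k_grid) < 2:
        raise ValueError("k_grid must contain at least two topic numbers")
    scores: dict[int, float] = {}
    for K in k_grid:
        lls = []
        for seed in seeds:
            model = LatentTopicModel(
                n_topics=K, alpha=alpha, beta=beta, iterations=iterations,
                seed=int(seed), algorithm=algorithm,
            ).fit(corpus)
            ll = log_likelihood(model)
            if score == "joint":
                ll += _collapsed_assignment_prior(model.n_pk_, alpha)
            lls.append(ll)
        scores[K] = float(np.mean(lls))
    best = max(scores, key=lambda k: (scores[k], -k))
    ties = [k for k, s in scores.items() if s == scores[best]]
    if len(ties) > 1:
        logger.warning("log-likelihood tie among K=%s; choosing smallest", ties)
        best = min(ties)
    return best, scores


def topic_memberships(
    model: LatentTopicModel, membership_epsilon: float = 1e-6
) -> list[dict[str, list[tuple[str, float]]]]:
    """Per-topic member genes and diseases with probabilities.

    A gene belongs to topic k when its expected count there exceeds
    ``membership_epsilon``; likewise a disease via its document-topic count.
    Lists are sorted by probability descending, ties lexicographic.
    """
    out = []
    for k in range(model.n_topics):
        genes = [
            (model.vocabulary_[i], float(model.phi_hat_[k, i]))
            for i in np.nonzero(model.n_ck_[k] > membership_epsilon)[0]
        ]
        diseases = [
            (model.documents_[j], float(model.theta_hat_[j, k]))
            for j in np.nonzero(model.n_pk_[:, k] > membership_epsilon)[0]
        ]
        key = lambda t: (-t[1], t[0])
        out.append({"genes": sorted(genes, key=key), "diseases": sorted(diseases, key=key)})
    return out


def rank_topics(model: LatentTopicModel) -> list[tuple[int, float]]:
    """Topics ranked by normalized posterior mass (descending, id tie-break)."""
    mass = model.n_ck_.sum(axis=1)
    total = mass.sum()
    if total <= 0:
        raise ValueError("model has no assigned mass")
    probs = mass / total
    order = sorted(range(model.n_topics), key=lambda k: (-probs[k], k))
    return [(k, float(probs[k])) for k in order]
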