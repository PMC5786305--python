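import numpy as np
import pytest

from topicnets import LatentTopicModel, simulate


def make_model(n_ck, n_pk, alpha=0.1, beta=0.01, vocabulary=None, documents=None):
    """Assemble a fitted-looking topic model from explicit count matrices."""
    from topicnets.lda import estimate_phi, estimate_theta

    n_ck = np.asarray(n_ck, dtype=float)
    n_pk = np.asarray(n_pk, dtype=float)
    model = LatentTopicModel(n_topics=n_ck.shape[0], alpha=alpha, beta=beta)
    model.n_ck_ = n_ck
    model.n_pk_ = n_pk
    model.phi_hat_ = estimate_phi(n_ck, beta)
    model.theta_hat_ = estimate_theta(n_pk, alpha)
    model.vocabulary_ = vocabulary or [f"G{i}" for i in range(n_ck.shape[1])]
    model.documents_ = documents or [f"d{j}" for j in range(n_pk.shape[0])]
    return model


@pytest.fixture(scope="session")
def small_planted():
    """Planted corpus small enough for fast fits but with clear topic structure."""
    return simulate.generate_corpus(
        K=5, P=80, C=60, alpha=0.1, beta=0.01, mean_doc_len=30, seed=7
    )


@pytest.fixture(scope="session")
def fitted_small(small_planted):
    model = LatentTopicModel(n_topics=5, iterations=200, seed=3).fit(
        small_planted.corpus
    )
    return model
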