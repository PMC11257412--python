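"""Shared fixtures: small random problem instances and posterior states."""

import numpy as np
import pytest

from logitcp.inference import (
    ARDPosterior,
    CouplingPosterior,
    FactorPosterior,
    ModelConfig,
    NoisePosterior,
    VariationalState,
    initialize_state,
)
from logitcp.similarity import SimilarityMatrix
from logitcp.tensorops import AssociationTensor


def random_similarity(n, rng, ids=None):
    """Random valid similarity matrix (kernel of random features)."""
    if n == 1:
        return SimilarityMatrix(np.ones((1, 1)), ids)
    X = rng.standard_normal((n, 3))
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    S = np.exp(-(D ** 2) / (2.0 * np.median(D[D > 0]) ** 2))
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, ids)


def make_instance(I=4, J=3, K=2, R=2, seed=0, density=0.3):
    """Random aligned (Y, Sm, Sd, cfg) instance for update-level tests."""
    rng = np.random.default_rng(seed)
    Yv = (rng.random((I, J, K)) < density).astype(float)
    Y = AssociationTensor(Yv)
    Sm = random_similarity(I, rng, Y.mirna_ids)
    Sd = random_similarity(J, rng, Y.disease_ids)
    cfg = ModelConfig(R=R, seed=seed, max_iter=50, tol=0.0)
    return Y, Sm, Sd, cfg


def randomized_state(Y, Sm, Sd, cfg, scale=0.7):
    """A state with non-trivial (random SPD) covariances and positive xi."""
    rng = np.random.default_rng(cfg.seed + 1)
    state = initialize_state(Y, Sm, Sd, cfg)
    R = cfg.R

    def spd(n):
        A = rng.standard_normal((n, n)) * scale
        return A @ A.T + np.eye(n)

    def factor(n):
        return FactorPosterior(
            rng.standard_normal((n, R)),
            np.stack([spd(R) for _ in range(n)]),
        )

    def coupling(n):
        return CouplingPosterior(
            rng.standard_normal((n, R)),
            np.stack([spd(n) for _ in range(R)]),
        )

    I, J, K = Y.shape
    state.G = factor(I)
    state.H = factor(J)
    state.W = factor(K)
    state.U = coupling(I)
    state.V = coupling(J)
    state.ard = ARDPosterior(1.0 + rng.random(R), 1.0 + rng.random(R))
    state.noise = NoisePosterior(
        2.0 + rng.random(), 1.0 + rng.random(), 2.0 + rng.random(), 1.0 + rng.random()
    )
    state.xi = rng.random((I, J, K)) + 0.5
    return state


@pytest.fixture
def tiny_instance():
    return make_instance(I=4, J=3, K=2, R=2, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
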