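"""Shared fixtures: random SPD matrices and small random mixture problems."""

import numpy as np
import pytest

from parsimix import MixtureParameters


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_spd(rng, p, scale=1.0):
    """Random symmetric positive-definite matrix with well-spread spectrum."""
    A = rng.standard_normal((p, p))
    Q, _ = np.linalg.qr(A)
    evals = scale * np.exp(rng.uniform(-1.5, 1.5, size=p))
    return (Q * evals) @ Q.T


def random_mixture_params(rng, k, p, sep=4.0):
    """Random valid mixture parameters with separated means."""
    w = rng.dirichlet(np.full(k, 5.0))
    means = rng.uniform(-sep, sep, size=(k, p))
    covs = np.stack([random_spd(rng, p) for _ in range(k)])
    return MixtureParameters(weights=w, means=means, covariances=covs)


@pytest.fixture
def spd_factory():
    return random_spd


@pytest.fixture
def mixture_factory():
    return random_mixture_params
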