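"""Mixture and classification log-likelihoods.

Log-densities are evaluated through triangular (Cholesky) factorization of
each component covariance rather than explicit inversion, batched over
components.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .exceptions import SingularCovarianceError
from .params import MixtureParameters

_LOG_2PI = np.log(2.0 * np.pi)


def component_log_densities(X: np.ndarray, params: MixtureParameters) -> np.ndarray:
    """Per-observation Gaussian log-densities ``log phi(x_i; mu_j, Sigma_j)``.

    Returns an (n, k) array.  Raises :class:`SingularCovarianceError` if any
    component covariance is not positive definite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    means = params.means
    covs = params.covariances
    k, p = means.shape
    try:
        L = np.linalg.cholesky(covs)  # (k, p, p)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("singular component covariance") from exc
    diff = X[None, :, :] - means[:, None, :]  # (k, n, p)
    # solve L y = diff^T for each component (batched forward substitution)
    y = np.linalg.solve(L, diff.transpose(0, 2, 1))  # (k, p, n)
    maha = np.einsum("kpn,kpn->kn", y, y)  # (k, n)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)  # (k,)
    logdens = -0.5 * (p * _LOG_2PI + logdet[:, None] + maha)  # (k, n)
    return logdens.T


def weighted_log_densities(X: np.ndarray, params: MixtureParameters) -> np.ndarray:
    """(n, k) array of ``log(pi_j phi(x_i; mu_j, Sigma_j))``."""
    return component_log_densities(X, params) + np.log(params.weights)[None, :]


def mixture_loglik(X: np.ndarray, params: MixtureParameters) -> float:
    """Mixture log-likelihood ``sum_i log sum_j pi_j phi(x_i; mu_j, Sigma_j)``."""
    return float(logsumexp(weighted_log_densities(X, params), axis=1).sum())


def classification_loglik(X: np.ndarray, params: MixtureParameters, labels: np.ndarray) -> float:
    """Classification log-likelihood of a hard partition.

    ``sum_j sum_{i in H_j} log(pi_j phi(x_i; mu_j, Sigma_j))`` with 0-based
    ``labels``; components with an empty class contribute zero.
    """
    labels = np.asarray(labels)
    lw = weighted_log_densities(X, params)
    if labels.shape[0] != lw.shape[0]:
        raise ValueError("labels length must match the number of observations")
    if labels.min() < 0 or labels.max() >= params.n_components:
        raise ValueError("labels out of range")
    return float(lw[np.arange(lw.shape[0]), labels].sum())
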