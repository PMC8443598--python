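"""Gaussian-mixture identification of intrinsic connectivity networks.

The reference embedding is clustered into N networks (default 7) by a
full-covariance Gaussian mixture whose EM is initialized from a template
atlas labeling, so component k stays identified with template network k.
Each aligned individual embedding is then re-clustered by EM warm-started
from the reference mixture's parameters; parcels take the network of
highest posterior probability.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

__all__ = ["GMMParameters", "NetworkAssignment", "fit_reference_gmm", "cluster_individual"]


@dataclasses.dataclass
class GMMParameters:
    weights: np.ndarray  # (N,)
    means: np.ndarray  # (N, K)
    covariances: np.ndarray  # (N, K, K)
    converged: bool
    n_iter: int
    log_likelihood: float
    reg_covar: float = 1e-6


@dataclasses.dataclass
class NetworkAssignment:
    """Hard labels (1..N) and posterior probabilities per parcel."""

    hard_labels: np.ndarray  # (P,)
    posteriors: np.ndarray  # (P, N)
    source: str = "reference"

    def __post_init__(self) -> None:
        row_sums = self.posteriors.sum(axis=1)
        if np.abs(row_sums - 1.0).max() > 1e-9:
            raise ValueError("posterior rows must sum to 1")
        if not np.array_equal(self.hard_labels, self.posteriors.argmax(axis=1) + 1):
            raise ValueError("hard labels must equal the posterior argmax")

    @property
    def n_networks(self) -> int:
        return self.posteriors.shape[1]


def _init_from_labels(x: np.ndarray, labels: np.ndarray, n_networks: int,
                      reg_covar: float):
    weights = np.empty(n_networks)
    means = np.empty((n_networks, x.shape[1]))
    covs = np.empty((n_networks, x.shape[1], x.shape[1]))
    for k in range(1, n_networks + 1):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            raise ValueError(f"init network {k} has no parcels")
        weights[k - 1] = members.size / x.shape[0]
        means[k - 1] = x[members].mean(axis=0)
        c = np.cov(x[members].T, bias=False) if members.size > 1 else np.zeros((x.shape[1],) * 2)
        c = np.atleast_2d(c) + reg_covar * np.eye(x.shape[1])
        covs[k - 1] = c
    return weights, means, covs


def _fit_gmm(x: np.ndarray, weights, means, covs, tol: float, max_iter: int,
             reg_covar: float) -> GaussianMixture:
    precisions = np.array([np.linalg.inv(c) for c in covs])
    gmm = GaussianMixture(
        n_components=len(weights), covariance_type="full",
        weights_init=weights, means_init=means, precisions_init=precisions,
        tol=tol, max_iter=max_iter, reg_covar=reg_covar, n_init=1,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence chatter handled below
        gmm.fit(x)
    return gmm


def fit_reference_gmm(reference, init_labels: np.ndarray, tol: float = 1e-6,
                      max_iter: int = 500, reg_covar: float = 1e-6):
    """Fit the reference mixture, initialized from a template atlas.

    EM starts from the per-template-network empirical weights, means and
    (regularized) full covariances of the reference embedding coordinates,
    which keeps component k identified with template network k.

    Returns ``(GMMParameters, NetworkAssignment)``.
    """
    x = np.asarray(reference.coordinates)
    labels = np.asarray(init_labels, dtype=int)
    n_net = labels.max()
    w, m, c = _init_from_labels(x, labels, n_net, reg_covar)
    gmm = _fit_gmm(x, w, m, c, tol, max_iter, reg_covar)
    post = gmm.predict_proba(x)
    hard = post.argmax(axis=1) + 1
    missing = sorted(set(range(1, n_net + 1)) - set(np.unique(hard)))
    if missing:
        warnings.warn(f"network(s) {missing} empty in reference assignment", stacklevel=2)
    params = GMMParameters(weights=gmm.weights_, means=gmm.means_,
                           covariances=gmm.covariances_, converged=bool(gmm.converged_),
                           n_iter=int(gmm.n_iter_), log_likelihood=float(gmm.lower_bound_),
                           reg_covar=reg_covar)
    return params, NetworkAssignment(hard_labels=hard, posteriors=post, source="reference")


def _assignment_under(params: GMMParameters, x: np.ndarray) -> np.ndarray:
    gmm = GaussianMixture(n_components=len(params.weights), covariance_type="full",
                          reg_covar=params.reg_covar)
    gmm.weights_ = params.weights
    gmm.means_ = params.means
    gmm.covariances_ = params.covariances
    gmm.precisions_cholesky_ = np.array(
        [np.linalg.cholesky(np.linalg.inv(c)) for c in params.covariances])
    return gmm.predict_proba(x)


def cluster_individual(aligned, reference_params: GMMParameters, refit: bool = True,
                       tol: float = 1e-6, max_iter: int = 500,
                       source: str = "subject") -> NetworkAssignment:
    """Network assignment of one aligned individual embedding.

    By default EM is refit on the subject's coordinates starting from the
    reference mixture parameters (components can drift, so after the refit
    each component is re-identified with the nearest reference mean; any
    remapping is reported). With ``refit=False``, or when the subject EM
    fails, parcels are scored under the unrefit reference mixture.
    """
    x = np.asarray(aligned.coordinates)
    if not refit:
        post = _assignment_under(reference_params, x)
        return NetworkAssignment(hard_labels=post.argmax(axis=1) + 1,
                                 posteriors=post, source=source)
    try:
        gmm = _fit_gmm(x, reference_params.weights, reference_params.means,
                       reference_params.covariances, tol, max_iter,
                       reference_params.reg_covar)
        if not np.isfinite(gmm.lower_bound_):
            raise ValueError("EM diverged")
    except (ValueError, np.linalg.LinAlgError) as err:
        warnings.warn(f"subject EM failed ({err}); assigned under the reference "
                      "mixture without refitting", stacklevel=2)
        post = _assignment_under(reference_params, x)
        return NetworkAssignment(hard_labels=post.argmax(axis=1) + 1,
                                 posteriors=post, source=source)
    post = gmm.predict_proba(x)
    # re-identify drifted components with the reference networks
    cost = np.linalg.norm(gmm.means_[:, None, :] - reference_params.means[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    if not np.array_equal(cols, np.arange(len(cols))):
        warnings.warn(f"subject components remapped to reference networks: {cols.tolist()}",
                      stacklevel=2)
        post = post[:, np.argsort(cols)]
    return NetworkAssignment(hard_labels=post.argmax(axis=1) + 1,
                             posteriors=post, source=source)
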