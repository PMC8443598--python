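"""Diffusion-map embedding of connectivity matrices and alignment.

The connectome is turned into a row-similarity affinity graph, embedded by
diffusion maps (anisotropic normalization exponent ``alpha``, diffusion
time ``t``), and each individual embedding is mapped into the space of a
group reference embedding by a closed-form change-of-basis operator.

Notation. With affinity W, degree D, the density-normalized kernel is
W' = D^-a W D^-a; the random-walk operator M = D'^-1 W'. Writing u_k for
the orthonormal eigenvectors of the symmetric conjugate of M with
eigenvalues 1 = l_0 > l_1 >= ..., the embedding coordinates are
x_k(i) = l_k^t * u_k(i) / u_0(i), k = 1..K; the trivial constant
eigenvector is dropped. Under this scaling the Euclidean distance between
rows equals (for K = P-1 exactly) the diffusion distance
sum_u (M^t_iu - M^t_ju)^2 / pi_u with pi the stationary distribution.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from numpy.linalg import lstsq
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

__all__ = ["EmbeddingConfig", "Embedding", "ChangeOfBasisOperator",
           "affinity", "diffusion_map", "build_reference", "change_of_basis"]


@dataclasses.dataclass
class EmbeddingConfig:
    """Diffusion-map settings.

    alpha=0.5 keeps global relations between data points (alpha=0 would be
    maximally density-sensitive, alpha=1 density-free); diffusion_time=1
    and 30 retained eigenvectors follow the reference workflow.
    """

    alpha: float = 0.5
    diffusion_time: float = 1.0
    n_components: int = 30
    kernel: str = "normalized_angle"  # or "cosine"

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.diffusion_time < 0:
            raise ValueError("diffusion_time must be >= 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.kernel not in ("normalized_angle", "cosine"):
            raise ValueError(f"unknown kernel: {self.kernel}")


@dataclasses.dataclass
class Embedding:
    """Low-dimensional diffusion coordinates (rows = parcels)."""

    coordinates: np.ndarray  # (P, K)
    eigenvalues: np.ndarray  # (K,) nonincreasing
    is_reference: bool = False
    is_aligned: bool = False
    config: EmbeddingConfig | None = None

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclasses.dataclass
class ChangeOfBasisOperator:
    matrix: np.ndarray  # (K, K)
    residual: float  # Frobenius norm of the alignment error


def affinity(fc, kernel: str = "normalized_angle") -> np.ndarray:
    """Row-similarity affinity of a sparsified connectivity matrix.

    Normalized-angle kernel: 1 - arccos(cosine(row_i, row_j)) / pi, in
    [0, 1], unit diagonal. The cosine kernel floors negative cosines at 0.
    """
    if not getattr(fc, "sparsified", False):
        raise ValueError("affinity expects a row-sparsified connectivity matrix")
    rows = np.asarray(fc.z_values, dtype=float)
    norms = np.linalg.norm(rows, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"all-zero row(s) in connectivity matrix: {bad.tolist()}")
    cos = np.clip((rows @ rows.T) / np.outer(norms, norms), -1.0, 1.0)
    if kernel == "normalized_angle":
        a = 1.0 - np.arccos(cos) / np.pi
    elif kernel == "cosine":
        a = cos
    else:
        raise ValueError(f"unknown kernel: {kernel}")
    a = np.clip(a, 0.0, 1.0)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def diffusion_map(aff: np.ndarray, cfg: EmbeddingConfig | None = None) -> Embedding:
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    Dense symmetric eigendecomposition (deterministic; no iterative
    solver). The per-column sign is fixed so the first entry of
    non-negligible magnitude is positive, which makes repeated runs
    bit-comparable.
    """
    cfg = cfg or EmbeddingConfig()
    a = np.asarray(aff, dtype=float)
    P = a.shape[0]
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("affinity must be square and symmetric")
    if a.min() < 0:
        raise ValueError("affinity must be non-negative")
    ncomp, _ = connected_components(a > 0, directed=False)
    if ncomp != 1:
        raise ValueError("affinity graph is disconnected")
    if cfg.n_components > P - 1:
        raise ValueError("n_components must be smaller than the matrix size")

    d = a.sum(axis=1)
    if cfg.alpha > 0:
        da = d ** (-cfg.alpha)
        w = a * np.outer(da, da)
    else:
        w = a
    d1 = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    s = w * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0
    evals, evecs = eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    u0 = evecs[:, 0]
    if u0.sum() < 0:  # Perron vector, fix global sign
        u0 = -u0
        evecs = evecs.copy()
        evecs[:, 0] = u0
    lam = evals[1:cfg.n_components + 1]
    psi = evecs[:, 1:cfg.n_components + 1] / u0[:, None]
    if (lam < 0).any() and cfg.diffusion_time != int(cfg.diffusion_time):
        raise ValueError("negative eigenvalues with non-integer diffusion time")
    coords = psi * lam[None, :] ** cfg.diffusion_time

    # deterministic sign convention per column
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * max(1.0, np.abs(col).max()))
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return Embedding(coordinates=coords, eigenvalues=lam, config=cfg)


def build_reference(mean_fc, cfg: EmbeddingConfig | None = None) -> Embedding:
    """Reference embedding of the group-mean connectivity matrix."""
    cfg = cfg or EmbeddingConfig()
    emb = diffusion_map(affinity(mean_fc, kernel=cfg.kernel), cfg)
    emb.is_reference = True
    return emb


def change_of_basis(individual: Embedding, reference: Embedding,
                    method: str = "lstsq"):
    """Map an individual embedding into the reference space.

    Solves O = argmin || Phi O - Psi ||_F over all P shared parcel rows in
    closed form (unconstrained least squares by default; ``method=
    "procrustes"`` restricts O to a rotation). Returns the operator and the
    aligned embedding Phi O.
    """
    phi = np.asarray(individual.coordinates)
    psi = np.asarray(reference.coordinates)
    if phi.shape != psi.shape:
        raise ValueError("individual and reference embeddings must share shape")
    if method == "lstsq":
        o, _, rank, _ = lstsq(phi, psi, rcond=None)
        if rank < phi.shape[1]:
            warnings.warn("rank-deficient embedding; used pseudoinverse solution",
                          stacklevel=2)
    elif method == "procrustes":
        o, _ = orthogonal_procrustes(phi, psi)
    else:
        raise ValueError(f"unknown alignment method: {method}")
    aligned_coords = phi @ o
    residual = float(np.linalg.norm(aligned_coords - psi))
    aligned = Embedding(coordinates=aligned_coords,
                        eigenvalues=individual.eigenvalues.copy(),
                        is_aligned=True, config=individual.config)
    return ChangeOfBasisOperator(matrix=o, residual=residual), aligned
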