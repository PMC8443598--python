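"""Idiosyncrasy descriptors.

A subject's functional network layout is compared against a canonical
reference layout in two complementary domains:

* the *spatial* domain, via geodesic distances along the cortical surface
  (surface distance SD, mean surface distance MSD, Dice/Jaccard overlap);
* the *embedding* domain, via squared Euclidean distances between aligned
  diffusion-map coordinates (diffusion distance DD).

A probabilistic view (entropy of group-average network probability maps)
and a cortical-hierarchy view (stratification along the principal gradient)
complete the descriptor set.

All descriptors operate at parcel resolution: geodesics are shortest paths
on the parcel graph, whose edge weights are mesh geodesic lengths between
the central vertices of adjacent parcels.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.stats import spearmanr

__all__ = [
    "GeodesicGraph",
    "build_geodesic_graph",
    "surface_distance",
    "diffusion_distance",
    "dice",
    "jaccard",
    "mean_surface_distance",
    "network_entropy",
    "network_size",
    "cortexwide_summary",
    "gradient_stratification",
    "network_summaries",
]


@dataclasses.dataclass
class GeodesicGraph:
    """Parcel-level geodesic graph.

    Parameters
    ----------
    weights : scipy.sparse matrix, shape (P, P)
        Symmetric adjacency with positive edge weights equal to the
        geodesic length (mesh length units) between the central vertices
        of adjacent parcels.
    centroids : ndarray, shape (P, 3), optional
        Parcel centroid coordinates on the sphere. Required for spin tests
        and direction-gated boundary shifts, not for distances.
    """

    weights: sp.spmatrix
    centroids: np.ndarray | None = None
    _dist: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.weights)
        if (abs(w - w.T) > 1e-10 * max(1.0, abs(w).max())).nnz > 0:
            raise ValueError("geodesic graph must be symmetric")
        if w.nnz and w.data.min() <= 0:
            raise ValueError("geodesic edge weights must be positive")
        ncomp, _ = connected_components(w, directed=False)
        if ncomp != 1:
            raise ValueError("geodesic graph must be connected")
        self.weights = w

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]

    @property
    def distance_matrix(self) -> np.ndarray:
        """All-pairs shortest-path distances (Dijkstra), cached."""
        if self._dist is None:
            self._dist = dijkstra(self.weights, directed=False)
        return self._dist

    def distance_to_set(self, parcels: np.ndarray) -> np.ndarray:
        """Distance from every parcel to the closest parcel in ``parcels``.

        Members of the set are at distance zero.
        """
        idx = np.asarray(parcels, dtype=int)
        if idx.size == 0:
            raise ValueError("empty parcel set")
        return self.distance_matrix[:, idx].min(axis=1)


def _vertex_graph(mesh) -> sp.csr_matrix:
    """Sparse vertex graph of a triangle mesh, edge weights = edge lengths."""
    faces = np.asarray(mesh.faces)
    verts = np.asarray(mesh.vertices)
    iu = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    iv = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    lengths = np.linalg.norm(verts[iu] - verts[iv], axis=1)
    n = len(verts)
    g = sp.coo_matrix((lengths, (iu, iv)), shape=(n, n)).tocsr()
    return g.maximum(g.T)


def build_geodesic_graph(mesh, parcellation) -> GeodesicGraph:
    """Build the parcel geodesic graph from a mesh and its parcellation.

    Two parcels are adjacent if they share at least one mesh edge; the edge
    weight is the geodesic distance along the mesh (vertex-level Dijkstra)
    between the two parcels' central vertices.
    """
    vg = _vertex_graph(mesh)
    labels = np.asarray(parcellation.vertex_to_parcel)  # ids 1..P
    P = parcellation.n_parcels
    central = np.asarray(parcellation.central_vertices)

    # parcel adjacency from mesh edges crossing parcel boundaries
    coo = sp.triu(vg, k=1).tocoo()
    pu = labels[coo.row] - 1
    pv = labels[coo.col] - 1
    cross = pu != pv
    pairs = {tuple(sorted((a, b))) for a, b in zip(pu[cross], pv[cross])}

    geod = dijkstra(vg, directed=False, indices=central)  # (P, n_vertices)
    rows, cols, data = [], [], []
    for a, b in sorted(pairs):
        d = geod[a, central[b]]
        rows += [a, b]
        cols += [b, a]
        data += [d, d]
    w = sp.coo_matrix((data, (rows, cols)), shape=(P, P)).tocsr()
    return GeodesicGraph(weights=w, centroids=np.asarray(parcellation.parcel_centroids))


# ---------------------------------------------------------------------------
# per-parcel descriptors


def surface_distance(subject, reference, geo: GeodesicGraph,
                     mask_agreeing: bool = False) -> np.ndarray:
    """Per-parcel surface distance (SD).

    For a parcel carrying subject network label ``c``, SD is the geodesic
    distance to the closest parcel assigned to ``c`` in the reference; it
    is zero wherever subject and reference labels agree. Those agreeing
    parcels enter group means as zeros by default; ``mask_agreeing=True``
    marks them NaN instead so means cover displaced parcels only.
    """
    sub = np.asarray(subject.hard_labels)
    ref = np.asarray(reference.hard_labels)
    sd = np.zeros(sub.size)
    for c in np.unique(sub):
        ref_set = np.flatnonzero(ref == c)
        if ref_set.size == 0:
            raise ValueError(f"network {c} absent from reference assignment")
        members = np.flatnonzero(sub == c)
        sd[members] = geo.distance_matrix[np.ix_(members, ref_set)].min(axis=1)
    sd[sub == ref] = np.nan if mask_agreeing else 0.0
    return sd


def diffusion_distance(aligned, reference, subject, reference_assignment) -> np.ndarray:
    """Per-parcel diffusion distance (DD).

    Squared Euclidean distance in the aligned embedding from each parcel to
    the closest reference parcel belonging to the same network.
    """
    phi = np.asarray(aligned.coordinates)
    psi = np.asarray(reference.coordinates)
    sub = np.asarray(subject.hard_labels)
    ref = np.asarray(reference_assignment.hard_labels)
    dd = np.zeros(sub.size)
    for c in np.unique(sub):
        ref_set = np.flatnonzero(ref == c)
        if ref_set.size == 0:
            raise ValueError(f"network {c} absent from reference assignment")
        members = np.flatnonzero(sub == c)
        diff = phi[members, None, :] - psi[None, ref_set, :]
        dd[members] = (diff**2).sum(axis=2).min(axis=1)
    return dd


# ---------------------------------------------------------------------------
# network-level descriptors


def _as_set(x: Iterable[int]) -> frozenset:
    return frozenset(int(i) for i in x)


def dice(a: Iterable[int], b: Iterable[int]) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two parcel sets."""
    A, B = _as_set(a), _as_set(b)
    if not A:
        raise ValueError("reference set A must be non-empty")
    if not B:
        return 0.0
    return 2.0 * len(A & B) / (len(A) + len(B))


def jaccard(a: Iterable[int], b: Iterable[int]) -> float:
    """Jaccard overlap |A∩B| / |A∪B| between two parcel sets."""
    A, B = _as_set(a), _as_set(b)
    if not A:
        raise ValueError("reference set A must be non-empty")
    if not B:
        return 0.0
    return len(A & B) / len(A | B)


def mean_surface_distance(a: Iterable[int], b: Iterable[int], geo: GeodesicGraph) -> float:
    """Symmetric mean surface distance between parcel sets A and B.

    MSD = (sum_{a in A} d(a, B) + sum_{b in B} d(b, A)) / (|A| + |B|),
    with d(x, S) the geodesic distance to the closest member of S (zero for
    members). Zero iff A == B.
    """
    A = np.asarray(sorted(_as_set(a)), dtype=int)
    B = np.asarray(sorted(_as_set(b)), dtype=int)
    if A.size == 0:
        raise ValueError("reference set A must be non-empty")
    if B.size == 0:
        raise ValueError("individual set B is empty; MSD undefined")
    D = geo.distance_matrix
    d_ab = D[np.ix_(A, B)].min(axis=1).sum()
    d_ba = D[np.ix_(B, A)].min(axis=1).sum()
    return float((d_ab + d_ba) / (A.size + B.size))


def network_entropy(posteriors: Sequence[np.ndarray]) -> np.ndarray:
    """Per-parcel entropy (nats) of the group-average probability maps.

    Posterior matrices (P x N) are averaged across the group first; the
    entropy of the averaged distribution measures how evenly probability
    mass spreads over networks at each location (0 = all subjects agree,
    ln N = uniform).
    """
    mats = [np.asarray(p) for p in posteriors]
    if not mats:
        raise ValueError("need at least one posterior matrix")
    pbar = np.mean(mats, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(pbar > 0, pbar * np.log(pbar), 0.0).sum(axis=1)
    return h


def one_hot_assignment(assignment, n_networks: int) -> np.ndarray:
    """Hard labels as a one-hot P x N matrix.

    Feeding one-hot matrices to :func:`network_entropy` yields the
    hard-label frequency variant of the group probability maps (the
    default pipeline averages GMM posteriors instead).
    """
    labels = np.asarray(assignment.hard_labels)
    out = np.zeros((labels.size, n_networks))
    out[np.arange(labels.size), labels - 1] = 1.0
    return out


def network_size(assignment, n_networks: int) -> np.ndarray:
    """Parcel counts per network id 1..n_networks (zeros allowed)."""
    labels = np.asarray(assignment.hard_labels)
    return np.bincount(labels, minlength=n_networks + 1)[1:]


def cortexwide_summary(scores: np.ndarray, reference_sizes: np.ndarray) -> float:
    """Cortex-wide score: average of per-network scores weighted by the
    reference network sizes."""
    s = np.asarray(scores, dtype=float)
    w = np.asarray(reference_sizes, dtype=float)
    if s.shape != w.shape:
        raise ValueError("scores and sizes must align by network")
    return float((w * s).sum() / w.sum())


@dataclasses.dataclass
class GradientStratification:
    bin_means: np.ndarray
    spearman_rho: float
    trend_defined: bool


def gradient_stratification(values: np.ndarray, reference, n_bins: int = 10) -> GradientStratification:
    """Stratify a per-parcel map along the principal gradient.

    Parcels are binned into quantiles of the first component of the
    reference embedding; reports per-bin means and the Spearman rank trend
    of bin mean versus bin index. A constant map has no defined trend and
    is reported as rho = 0 with ``trend_defined=False``.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(reference.coordinates)[:, 0]
    if n_bins > v.size:
        raise ValueError("n_bins exceeds the number of parcels")
    edges = np.quantile(g, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, g, side="right") - 1, 0, n_bins - 1)
    means = np.array([v[idx == b].mean() if np.any(idx == b) else np.nan for b in range(n_bins)])
    ok = ~np.isnan(means)
    if np.allclose(means[ok], means[ok][0]):
        return GradientStratification(means, 0.0, False)
    rho = spearmanr(np.arange(n_bins)[ok], means[ok]).statistic
    return GradientStratification(means, float(rho), True)


def network_summaries(subject, reference, geo: GeodesicGraph, n_networks: int,
                      sd: np.ndarray | None = None, dd: np.ndarray | None = None) -> dict:
    """Per-network Dice/Jaccard/MSD/size (and mean SD/DD when provided)
    of one subject against the reference assignment.

    Returns a dict of arrays indexed by network id - 1. A network empty in
    the subject gets Dice = Jaccard = 0 and NaN MSD.
    """
    sub = np.asarray(subject.hard_labels)
    ref = np.asarray(reference.hard_labels)
    out = {k: np.full(n_networks, np.nan) for k in ("dice", "jaccard", "msd", "size", "mean_sd", "mean_dd")}
    for c in range(1, n_networks + 1):
        A = np.flatnonzero(ref == c)
        B = np.flatnonzero(sub == c)
        out["size"][c - 1] = B.size
        out["dice"][c - 1] = dice(A, B) if B.size else 0.0
        out["jaccard"][c - 1] = jaccard(A, B) if B.size else 0.0
        if B.size:
            out["msd"][c - 1] = mean_surface_distance(A, B, geo)
        if sd is not None:
            out["mean_sd"][c - 1] = sd[A].mean()
        if dd is not None:
            out["mean_dd"][c - 1] = dd[A].mean()
    return out
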