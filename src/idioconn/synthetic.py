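"""Synthetic cohorts with controllable network idiosyncrasy.

The generator emulates a two-group, multi-site resting-state cohort at
parcel resolution. Cortical geometry is an icosphere mesh carved into
contiguous parcels; a template of N contiguous "intrinsic connectivity
networks" is laid over the parcels. Each simulated subject displaces the
template network boundaries by a geodesic front propagation whose
magnitude is the ground-truth idiosyncrasy of that subject, and emits
parcel time series from a latent-signal block model (one latent signal per
network plus a global component). Group membership, site, age and a
severity score coupled to the realized boundary shift provide the
phenotypic structure needed by the downstream statistics.

Every function is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse.csgraph import connected_components, dijkstra

from .idiosyncrasy import GeodesicGraph, build_geodesic_graph, _vertex_graph

__all__ = [
    "SurfaceMesh",
    "Parcellation",
    "GroundTruth",
    "TimeSeriesMatrix",
    "CohortConfig",
    "ShiftConfig",
    "TimeSeriesConfig",
    "Scenario",
    "SyntheticDataset",
    "make_sphere_mesh",
    "make_parcellation",
    "make_reference_networks",
    "simulate_cohort",
    "assign_severity",
    "shift_networks",
    "simulate_subject_timeseries",
    "simulate_dataset",
]


@dataclasses.dataclass
class SurfaceMesh:
    """Spherical triangle mesh (vertices on a sphere of ``sphere_radius``)."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    sphere_radius: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        r = np.linalg.norm(self.vertices, axis=1)
        if np.abs(r - self.sphere_radius).max() > 1e-6 * self.sphere_radius:
            raise ValueError("vertices do not lie on the sphere surface")
        if not np.isin(np.arange(len(self.vertices)), self.faces).all():
            raise ValueError("every vertex must be referenced by at least one face")
        ncomp, _ = connected_components(_vertex_graph(self), directed=False)
        if ncomp != 1:
            raise ValueError("mesh edge graph must be connected")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclasses.dataclass
class Parcellation:
    """Hard assignment of mesh vertices to parcels (ids 1..P)."""

    vertex_to_parcel: np.ndarray  # (V,) int in 1..P
    parcel_centroids: np.ndarray  # (P, 3)
    central_vertices: np.ndarray  # (P,) vertex index closest to each centroid
    n_parcels: int


@dataclasses.dataclass
class GroundTruth:
    """Ground-truth network layouts used for parameter-recovery tests."""

    reference_labels: np.ndarray  # (P,) int in 1..N
    subject_labels: pd.DataFrame  # subjects x parcels
    shift_magnitude: pd.DataFrame  # subjects x networks, configured magnitudes
    realized_shift: pd.DataFrame  # subjects x networks, realized displacement


@dataclasses.dataclass
class TimeSeriesMatrix:
    """Parcel time series, shape (parcels, timepoints), sampled every ``tr`` s."""

    values: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("time series contain non-finite values")
        if (self.values.var(axis=1) <= 0).any():
            raise ValueError("every parcel must have positive variance")


# ---------------------------------------------------------------------------
# geometry


def make_sphere_mesh(n_subdivisions: int, radius: float = 100.0) -> SurfaceMesh:
    """Icosphere mesh: 20 * 4**n faces, vertices projected onto the sphere."""
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=n_subdivisions, radius=radius)
    verts = np.asarray(m.vertices, dtype=float)
    verts *= radius / np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(vertices=verts, faces=np.asarray(m.faces, dtype=int), sphere_radius=radius)


def _farthest_point_sample(dist_from, n_points: int, n_total: int, rng: np.random.Generator):
    """Greedy farthest-point sampling; returns (indices, dist rows).

    ``dist_from(i)`` must return graph distances from node i to all nodes.
    """
    first = int(rng.integers(n_total))
    seeds = [first]
    rows = [dist_from(first)]
    mind = rows[0].copy()
    while len(seeds) < n_points:
        nxt = int(np.argmax(mind))
        seeds.append(nxt)
        rows.append(dist_from(nxt))
        mind = np.minimum(mind, rows[-1])
    return np.array(seeds), np.vstack(rows)


def make_parcellation(mesh: SurfaceMesh, n_parcels: int, seed: int) -> Parcellation:
    """Contiguous parcels by farthest-point-sampled seeds + graph Voronoi.

    Seed vertices are chosen by greedy farthest-point sampling on the mesh
    geodesic graph; every vertex is then assigned to its nearest seed
    (ties to the lower seed index), which yields connected cells.
    """
    V = mesh.n_vertices
    if n_parcels > V:
        raise ValueError("n_parcels cannot exceed the number of vertices")
    rng = np.random.default_rng(seed)
    vg = _vertex_graph(mesh)
    seeds, dists = _farthest_point_sample(
        lambda i: dijkstra(vg, directed=False, indices=i), n_parcels, V, rng
    )
    assign = np.argmin(dists, axis=0)  # ties -> lower seed index
    labels = assign + 1

    centroids = np.empty((n_parcels, 3))
    central = np.empty(n_parcels, dtype=int)
    for p in range(n_parcels):
        members = np.flatnonzero(assign == p)
        c = mesh.vertices[members].mean(axis=0)
        norm = np.linalg.norm(c)
        c = c * (mesh.sphere_radius / norm) if norm > 0 else mesh.vertices[members[0]]
        centroids[p] = c
        central[p] = members[np.argmin(np.linalg.norm(mesh.vertices[members] - c, axis=1))]
    return Parcellation(vertex_to_parcel=labels, parcel_centroids=centroids,
                        central_vertices=central, n_parcels=n_parcels)


def make_reference_networks(parcellation: Parcellation, n_networks: int, seed: int,
                            geodesic: GeodesicGraph,
                            size_bias: tuple | None = None) -> np.ndarray:
    """Contiguous template network territories over the parcels (ids 1..N).

    Farthest-point-sampled seeds followed by a (multiplicatively weighted)
    graph Voronoi assignment on the parcel geodesic graph; emulates a
    canonical N-network atlas. ``size_bias`` scales each network's growth
    speed — real intrinsic networks differ substantially in territory, and
    unequal sizes are what couples boundary shifts to degree centrality.
    Weighted cells can occasionally fragment; disconnected fragments are
    reassigned to the majority adjacent network so every territory stays
    contiguous.
    """
    P = parcellation.n_parcels
    if n_networks > P:
        raise ValueError("n_networks cannot exceed the number of parcels")
    rng = np.random.default_rng(seed)
    D = geodesic.distance_matrix
    _, dists = _farthest_point_sample(lambda i: D[i], n_networks, P, rng)
    if size_bias is not None:
        w = np.asarray(size_bias, dtype=float)
        if w.size != n_networks or (w <= 0).any():
            raise ValueError("size_bias must hold one positive weight per network")
        dists = dists / w[:, None]
    labels = np.argmin(dists, axis=0) + 1
    return _repair_contiguity(labels, geodesic, n_networks)


def _repair_contiguity(labels: np.ndarray, geodesic: GeodesicGraph,
                       n_networks: int) -> np.ndarray:
    """Reassign disconnected fragments of any network to a neighboring one."""
    adj = (geodesic.weights > 0).tocsr()
    labels = labels.copy()
    for _ in range(n_networks * 4):  # repairs can cascade; bounded loop
        changed = False
        for k in range(1, n_networks + 1):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                continue
            ncomp, comp = connected_components(adj[np.ix_(members, members)],
                                               directed=False)
            if ncomp == 1:
                continue
            sizes = np.bincount(comp)
            for frag in np.flatnonzero(sizes < sizes.max()):
                frag_parcels = members[comp == frag]
                neigh = adj[frag_parcels].indices
                neigh_labels = labels[neigh]
                neigh_labels = neigh_labels[neigh_labels != k]
                if neigh_labels.size == 0:
                    continue
                labels[frag_parcels] = np.bincount(neigh_labels).argmax()
                changed = True
        if not changed:
            return labels
    raise RuntimeError("could not repair network contiguity")


# ---------------------------------------------------------------------------
# cohort


@dataclasses.dataclass
class CohortConfig:
    """Demographics of the simulated cohort.

    Site weights follow the relative sizes of the five acquisition sites of
    the multi-site cohort the generator emulates; ages are drawn from a
    truncated normal matching its mean and dispersion (years); framewise
    displacement (mm) is lognormal with a small mass above the QC cutoff.
    """

    n_typical: int = 40
    n_atypical: int = 40
    site_names: tuple = ("site1", "site2", "site3", "site4", "site5")
    site_weights: tuple = (32, 126, 42, 37, 92)
    age_mean: float = 18.4
    age_sd: float = 8.0
    age_min: float = 5.0
    age_max: float = 50.0
    p_male: float = 0.8
    fd_log_mean: float = float(np.log(0.12))
    fd_log_sd: float = 0.45
    severity_intercept: float = -2.0
    severity_coupling: float = 0.35  # b: score units per length unit of shift
    severity_noise_sd: float = 0.5
    severity_min: float = 1.0
    severity_max: float = 10.0


def simulate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Simulate the cohort table (severity filled in later from realized shift).

    Columns: id, group ('typical'/'atypical'), site, age, sex, fd, severity
    (NaN placeholder; see :func:`assign_severity`).
    """
    if config.n_typical <= 0 or config.n_atypical <= 0:
        raise ValueError("group sizes must be positive")
    rng = np.random.default_rng(seed)
    n = config.n_typical + config.n_atypical
    group = np.array(["typical"] * config.n_typical + ["atypical"] * config.n_atypical)
    w = np.asarray(config.site_weights, dtype=float)
    site = rng.choice(config.site_names, size=n, p=w / w.sum())
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n),
                  config.age_min, config.age_max)
    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    fd = np.exp(rng.normal(config.fd_log_mean, config.fd_log_sd, size=n))
    ids = [f"sub-{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame({
        "id": ids, "group": group, "site": site, "age": age,
        "sex": sex, "fd": fd, "severity": np.nan,
    })


def assign_severity(cohort: pd.DataFrame, realized_mean_shift: Mapping[str, float],
                    config: CohortConfig, seed: int) -> pd.DataFrame:
    """Fill the severity column for atypical subjects.

    severity = a + b * (realized mean shift) + noise, clipped to the score
    range; NaN for typical subjects. With zero noise and b > 0 severity is
    a strictly increasing function of the realized shift.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    atyp = out["group"] == "atypical"
    shift = out.loc[atyp, "id"].map(realized_mean_shift).to_numpy(dtype=float)
    noise = rng.normal(0.0, config.severity_noise_sd, size=int(atyp.sum()))
    css = config.severity_intercept + config.severity_coupling * shift + noise
    out.loc[atyp, "severity"] = np.clip(css, config.severity_min, config.severity_max)
    return out


# ---------------------------------------------------------------------------
# boundary shifting


def shift_networks(reference_labels: np.ndarray, magnitudes: np.ndarray,
                   geodesic: GeodesicGraph, seed: int | np.random.Generator):
    """Displace network boundaries by a geodesic front propagation.

    For every network ``k`` with magnitude ``m > 0`` a random tangential
    direction is drawn; parcels of other networks on the leading side whose
    geodesic distance to the reference territory of ``k`` is at most ``m``
    are relabeled into ``k``, and parcels of ``k`` on the trailing side
    within ``m`` of the territory boundary are released to their nearest
    other reference network. Zero magnitude leaves the labels untouched.

    Returns ``(subject_labels, realized)`` where ``realized[k-1]`` is the
    mean geodesic displacement of the parcels relabeled for network ``k``
    (0 when none moved).

    A magnitude exceeding the geodesic diameter of the network's reference
    territory would displace the network past its own footprint (the
    territory would vanish as a coherent entity) and raises; annexation
    never consumes the last parcel of a donor network, so every network
    stays non-empty.
    """
    ref = np.asarray(reference_labels, dtype=int)
    mags = np.asarray(magnitudes, dtype=float)
    if (mags < 0).any():
        raise ValueError("shift magnitudes must be non-negative")
    n_net = mags.size
    if geodesic.centroids is None:
        raise ValueError("geodesic graph must carry parcel centroids")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D = geodesic.distance_matrix
    cent = geodesic.centroids
    labels = ref.copy()
    realized = np.zeros(n_net)

    for k in range(1, n_net + 1):
        m = mags[k - 1]
        if m <= 0:
            continue
        ref_set = np.flatnonzero(ref == k)
        if ref_set.size == 0:
            raise ValueError(f"network {k} empty in reference labels")
        diam = D[np.ix_(ref_set, ref_set)].max()
        if m > diam:
            raise ValueError(
                f"shift magnitude {m:g} exceeds the diameter {diam:g} of "
                f"network {k}; the network would vanish")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        net_c = cent[ref_set].mean(axis=0)
        proj = (cent - net_c) @ u
        d_to_net = D[:, ref_set].min(axis=1)
        comp = np.flatnonzero(ref != k)
        d_to_boundary = D[:, comp].min(axis=1)  # for members of k

        moved = []
        # leading side: annex foreign parcels within m of the territory
        gain = np.flatnonzero((ref != k) & (d_to_net <= m) & (proj > 0))
        for p in gain[np.argsort(d_to_net[gain], kind="stable")]:
            donor = labels[p]
            if donor == k or np.count_nonzero(labels == donor) <= 1:
                continue  # never consume a donor's last parcel
            labels[p] = k
            moved.append(d_to_net[p])
        # trailing side: release own parcels within m of the boundary
        lose = np.flatnonzero((ref == k) & (labels == k)
                              & (d_to_boundary <= m) & (proj < 0))
        for p in lose[np.argsort(d_to_boundary[lose], kind="stable")]:
            if np.count_nonzero(labels == k) <= 1:
                continue
            others = [j for j in range(1, n_net + 1) if j != k]
            dist_j = [D[p, np.flatnonzero(ref == j)].min() for j in others]
            labels[p] = others[int(np.argmin(dist_j))]
            moved.append(d_to_boundary[p])
        realized[k - 1] = float(np.mean(moved)) if moved else 0.0

    counts = np.bincount(labels, minlength=n_net + 1)[1:]
    if (counts == 0).any():
        raise ValueError("a network vanished under the configured shifts")
    return labels, realized


# ---------------------------------------------------------------------------
# time series


@dataclasses.dataclass
class TimeSeriesConfig:
    n_timepoints: int = 300
    tr: float = 2.0
    within_network_corr: float = 0.5
    global_coupling: float = 0.2  # shared variance fraction between network latents
    site_amplitude: tuple = (1.0, 0.9, 1.1, 0.95, 1.05)


def simulate_subject_timeseries(subject_labels: np.ndarray, n_timepoints: int,
                                within_network_corr: float,
                                seed: int | np.random.Generator,
                                noise_sd: float | None = None,
                                global_coupling: float = 0.0,
                                amplitude: float = 1.0,
                                tr: float = 2.0) -> TimeSeriesMatrix:
    """Latent-signal block model.

    Each parcel follows its network's unit-variance latent signal plus
    independent Gaussian noise: x_p = g_{k(p)} + sigma * eps_p. The noise
    scale is chosen so that the expected within-network correlation equals
    ``within_network_corr`` (r = 1 / (1 + sigma^2)); pass ``noise_sd`` to
    override it directly. Network latents share a ``global_coupling``
    fraction of variance with a common global signal, so cross-network
    correlations are rho * r. ``amplitude`` scales the whole series
    (site effects enter here and do not affect correlations).
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be at least 10")
    if not 0 < within_network_corr < 1:
        raise ValueError("within_network_corr must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(subject_labels, dtype=int)
    nets = np.unique(labels)
    sigma = float(noise_sd) if noise_sd is not None else float(np.sqrt(1.0 / within_network_corr - 1.0))

    g_global = rng.standard_normal(n_timepoints)
    latents = {}
    for k in nets:
        e = rng.standard_normal(n_timepoints)
        latents[k] = np.sqrt(1.0 - global_coupling) * e + np.sqrt(global_coupling) * g_global
    x = np.empty((labels.size, n_timepoints))
    for i, k in enumerate(labels):
        x[i] = latents[k] + sigma * rng.standard_normal(n_timepoints)
    return TimeSeriesMatrix(values=amplitude * x, tr=tr)


# ---------------------------------------------------------------------------
# full scenario


@dataclasses.dataclass
class ShiftConfig:
    """Ground-truth boundary-shift magnitudes (mesh length units).

    Networks listed in ``increase_networks`` are shifted more in the
    atypical group; the single ``decrease_network`` is shifted more in the
    typical group (so sign recovery can be tested in both directions); all
    other networks share the baseline. Magnitudes grow linearly with age
    (same slope in both groups) and carry subject-level Gaussian noise.

    With the default 100-unit sphere and 200 parcels, adjacent parcel
    centroids sit roughly 25 units apart, so the 30-unit baseline displaces
    about one ring of boundary parcels and the 55-unit shifted value two.
    """

    typical_base: float = 30.0
    atypical_increase: float = 55.0
    increase_networks: tuple = (1, 2, 3, 4)
    decrease_network: int = 5
    decrease_typical: float = 70.0
    decrease_atypical: float = 10.0
    age_slope: float = 0.3  # units per year, identical in both groups
    age_reference: float = 18.0
    subject_sd: float = 8.0

    def mean_magnitudes(self, group: str, n_networks: int) -> np.ndarray:
        """Mean magnitude per network; ids beyond n_networks are ignored."""
        m = np.full(n_networks, self.typical_base)
        if group == "atypical":
            for k in self.increase_networks:
                if k <= n_networks:
                    m[k - 1] = self.atypical_increase
        if self.decrease_network <= n_networks:
            m[self.decrease_network - 1] = (self.decrease_atypical if group == "atypical"
                                            else self.decrease_typical)
        return m


@dataclasses.dataclass
class Scenario:
    """Complete study conditions for one synthetic cohort."""

    mesh_subdivisions: int = 4
    sphere_radius: float = 100.0
    n_parcels: int = 200
    n_networks: int = 7
    network_size_bias: tuple = (1.4, 1.2, 1.1, 1.0, 0.95, 0.9, 0.85)
    geometry_seed: int = 12345
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    shift: ShiftConfig = dataclasses.field(default_factory=ShiftConfig)
    timeseries: TimeSeriesConfig = dataclasses.field(default_factory=TimeSeriesConfig)

    @classmethod
    def low_noise(cls, **kw) -> "Scenario":
        """High-SNR variant used for exact label-recovery checks."""
        sc = cls(**kw)
        sc.timeseries = dataclasses.replace(sc.timeseries,
                                            within_network_corr=0.8, n_timepoints=400)
        return sc


@dataclasses.dataclass
class SyntheticDataset:
    mesh: SurfaceMesh
    parcellation: Parcellation
    geodesic: GeodesicGraph
    template_labels: np.ndarray
    cohort: pd.DataFrame
    ground_truth: GroundTruth
    timeseries: dict  # id -> TimeSeriesMatrix


def _geometry(scenario: Scenario):
    mesh = make_sphere_mesh(scenario.mesh_subdivisions, scenario.sphere_radius)
    parc = make_parcellation(mesh, scenario.n_parcels, scenario.geometry_seed)
    geo = build_geodesic_graph(mesh, parc)
    bias = getattr(scenario, "network_size_bias", None)
    template = make_reference_networks(parc, scenario.n_networks,
                                       scenario.geometry_seed, geo,
                                       size_bias=bias)
    return mesh, parc, geo, template


_GEOMETRY_CACHE: dict = {}


def scenario_geometry(scenario: Scenario):
    """Mesh, parcellation, geodesic graph and network template of a scenario.

    Geometry depends only on (subdivisions, radius, n_parcels, n_networks,
    geometry_seed) and is cached per process.
    """
    key = (scenario.mesh_subdivisions, scenario.sphere_radius,
           scenario.n_parcels, scenario.n_networks,
           tuple(scenario.network_size_bias) if scenario.network_size_bias else None,
           scenario.geometry_seed)
    if key not in _GEOMETRY_CACHE:
        _GEOMETRY_CACHE[key] = _geometry(scenario)
    return _GEOMETRY_CACHE[key]


def simulate_dataset(scenario: Scenario, seed: int) -> SyntheticDataset:
    """Simulate a full dataset: geometry, cohort, shifted labels, time series.

    The cohort seed controls everything stochastic except the geometry,
    which is pinned by ``scenario.geometry_seed`` so that all cohorts of a
    scenario share the same mesh, parcellation and network template.
    """
    mesh, parc, geo, template = scenario_geometry(scenario)
    ss = np.random.SeedSequence(seed)
    s_cohort, s_shift, s_ts, s_sev = [np.random.default_rng(c) for c in ss.spawn(4)]

    cohort = simulate_cohort(scenario.cohort, s_cohort)

    n_net = scenario.n_networks
    sh = scenario.shift
    # subject magnitudes are capped below each territory's geodesic diameter
    # (the validity bound of the front-propagation model)
    D = geo.distance_matrix
    diams = np.array([
        D[np.ix_(np.flatnonzero(template == k), np.flatnonzero(template == k))].max()
        for k in range(1, n_net + 1)])
    mag_cap = 0.95 * diams
    sub_labels = {}
    shift_rows, realized_rows = [], []
    tsc = scenario.timeseries
    site_amp = dict(zip(scenario.cohort.site_names, tsc.site_amplitude))
    series = {}
    for row in cohort.itertuples(index=False):
        base = sh.mean_magnitudes(row.group, n_net)
        mags = base + sh.age_slope * (row.age - sh.age_reference)
        mags = np.clip(mags + s_shift.normal(0.0, sh.subject_sd, size=n_net),
                       0.0, mag_cap)
        labels, realized = shift_networks(template, mags, geo, s_shift)
        sub_labels[row.id] = labels
        shift_rows.append(mags)
        realized_rows.append(realized)
        series[row.id] = simulate_subject_timeseries(
            labels, tsc.n_timepoints, tsc.within_network_corr, s_ts,
            global_coupling=tsc.global_coupling,
            amplitude=site_amp.get(row.site, 1.0), tr=tsc.tr)

    ids = cohort["id"].tolist()
    net_cols = [f"net{k}" for k in range(1, n_net + 1)]
    shift_df = pd.DataFrame(shift_rows, index=ids, columns=net_cols)
    realized_df = pd.DataFrame(realized_rows, index=ids, columns=net_cols)
    cohort = assign_severity(cohort, realized_df.mean(axis=1).to_dict(),
                             scenario.cohort, s_sev)
    gt = GroundTruth(
        reference_labels=template,
        subject_labels=pd.DataFrame({i: sub_labels[i] for i in ids}).T,
        shift_magnitude=shift_df,
        realized_shift=realized_df,
    )
    return SyntheticDataset(mesh=mesh, parcellation=parc, geodesic=geo,
                            template_labels=template, cohort=cohort,
                            ground_truth=gt, timeseries=series)
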