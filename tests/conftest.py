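import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from idioconn.idiosyncrasy import GeodesicGraph, build_geodesic_graph
from idioconn.synthetic import (Scenario, make_parcellation,
                                make_reference_networks, make_sphere_mesh,
                                simulate_dataset)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def path_graph(weights) -> GeodesicGraph:
    """Chain graph with given consecutive edge weights."""
    w = np.asarray(weights, dtype=float)
    n = w.size + 1
    rows = np.arange(n - 1)
    g = sp.coo_matrix((w, (rows, rows + 1)), shape=(n, n)).tocsr()
    return GeodesicGraph(weights=g.maximum(g.T))


def random_geodesic_graph(n: int, rng: np.random.Generator) -> GeodesicGraph:
    """Connected random graph with positive weights (ring + chords)."""
    rows = list(range(n))
    cols = [(i + 1) % n for i in range(n)]
    data = list(rng.uniform(0.5, 2.0, size=n))
    extra = rng.integers(0, n, size=(n, 2))
    for a, b in extra:
        if a != b:
            rows.append(int(a))
            cols.append(int(b))
            data.append(float(rng.uniform(0.5, 2.0)))
    g = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    g = g.maximum(g.T)
    return GeodesicGraph(weights=g)


@pytest.fixture(scope="session")
def small_geometry():
    """Coarse sphere with 40 parcels and a 5-network template."""
    mesh = make_sphere_mesh(2, radius=100.0)
    parc = make_parcellation(mesh, 40, seed=7)
    geo = build_geodesic_graph(mesh, parc)
    template = make_reference_networks(parc, 5, seed=7, geodesic=geo)
    return mesh, parc, geo, template


def tiny_scenario(n_per_group: int = 4, **kw) -> Scenario:
    """Small-but-complete scenario for fast end-to-end tests."""
    sc = Scenario(mesh_subdivisions=3, n_parcels=80, n_networks=5,
                  network_size_bias=(1.3, 1.1, 1.0, 0.9, 0.8), **kw)
    sc.cohort = dataclasses.replace(sc.cohort, n_typical=n_per_group,
                                    n_atypical=n_per_group)
    sc.timeseries = dataclasses.replace(sc.timeseries, n_timepoints=150)
    return sc


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(tiny_scenario(), seed=3)
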