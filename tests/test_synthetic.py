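"""Generator tests: geometry, cohort, boundary shifts, time series."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm, spearmanr

from idioconn.idiosyncrasy import mean_surface_distance
from idioconn.synthetic import (CohortConfig, assign_severity,
                                make_parcellation, make_reference_networks,
                                make_sphere_mesh, shift_networks, simulate_cohort,
                                simulate_dataset, simulate_subject_timeseries)

from conftest import tiny_scenario


class TestSphereMesh:
    @pytest.mark.parametrize("n_sub, n_v, n_f", [(0, 12, 20), (1, 42, 80), (2, 162, 320)])
    def test_icosphere_counts(self, n_sub, n_v, n_f):
        m = make_sphere_mesh(n_sub, radius=10.0)
        assert m.n_vertices == n_v
        assert len(m.faces) == n_f

    def test_vertices_on_sphere(self):
        m = make_sphere_mesh(3, radius=42.0)
        r = np.linalg.norm(m.vertices, axis=1)
        assert np.abs(r - 42.0).max() < 1e-6 * 42.0

    def test_negative_subdivisions_rejected(self):
        with pytest.raises(ValueError):
            make_sphere_mesh(-1)


class TestParcellation:
    def test_single_parcel(self):
        m = make_sphere_mesh(1)
        p = make_parcellation(m, 1, seed=0)
        assert (p.vertex_to_parcel == 1).all()

    def test_one_parcel_per_vertex(self):
        m = make_sphere_mesh(0)
        p = make_parcellation(m, 12, seed=0)
        assert sorted(p.vertex_to_parcel) == list(range(1, 13))

    def test_deterministic(self):
        m = make_sphere_mesh(2)
        a = make_parcellation(m, 20, seed=5)
        b = make_parcellation(m, 20, seed=5)
        assert np.array_equal(a.vertex_to_parcel, b.vertex_to_parcel)

    def test_too_many_parcels_rejected(self):
        m = make_sphere_mesh(0)
        with pytest.raises(ValueError):
            make_parcellation(m, 13, seed=0)

    def test_parcels_nonempty_and_contiguous(self):
        from idioconn.idiosyncrasy import _vertex_graph

        m = make_sphere_mesh(2)
        p = make_parcellation(m, 25, seed=1)
        vg = _vertex_graph(m)
        for k in range(1, 26):
            members = np.flatnonzero(p.vertex_to_parcel == k)
            assert members.size > 0
            ncomp, _ = connected_components(vg[np.ix_(members, members)],
                                            directed=False)
            assert ncomp == 1


class TestReferenceNetworks:
    def test_single_network(self, small_geometry):
        _, parc, geo, _ = small_geometry
        labels = make_reference_networks(parc, 1, seed=0, geodesic=geo)
        assert (labels == 1).all()

    def test_default_has_all_labels(self, small_geometry):
        _, parc, geo, template = small_geometry
        assert sorted(np.unique(template)) == [1, 2, 3, 4, 5]

    def test_networks_contiguous(self, small_geometry):
        _, parc, geo, template = small_geometry
        adj = (geo.weights > 0).tocsr()
        for k in np.unique(template):
            members = np.flatnonzero(template == k)
            ncomp, _ = connected_components(adj[np.ix_(members, members)],
                                            directed=False)
            assert ncomp == 1

    def test_size_bias_orders_sizes(self, small_geometry):
        _, parc, geo, _ = small_geometry
        labels = make_reference_networks(parc, 3, seed=2, geodesic=geo,
                                         size_bias=(2.0, 1.0, 0.5))
        sizes = np.bincount(labels)[1:]
        assert sizes[0] > sizes[2]


class TestCohort:
    def test_group_sizes(self):
        cfg = CohortConfig(n_typical=10, n_atypical=10)
        df = simulate_cohort(cfg, seed=0)
        assert len(df) == 20
        assert (df["group"] == "typical").sum() == 10
        assert df["id"].is_unique
        assert (df["fd"] >= 0).all()

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(CohortConfig(n_typical=0), seed=0)

    def test_severity_rank_coupling_noiseless(self):
        cfg = CohortConfig(n_typical=5, n_atypical=15, severity_noise_sd=0.0,
                           severity_coupling=0.1, severity_intercept=0.0,
                           severity_min=0.0, severity_max=np.inf)
        df = simulate_cohort(cfg, seed=1)
        shift = {i: s for i, s in zip(df["id"], np.random.default_rng(0).uniform(0, 50, len(df)))}
        out = assign_severity(df, shift, cfg, seed=2)
        atyp = out[out["group"] == "atypical"]
        rho = spearmanr(atyp["severity"], [shift[i] for i in atyp["id"]]).statistic
        assert rho == pytest.approx(1.0)
        assert out.loc[out["group"] == "typical", "severity"].isna().all()

    def test_fd_exclusion_rate_matches_lognormal(self):
        # expected P(fd > 0.3) from the lognormal parameters, compared to the
        # empirical exclusion fraction over many simulated cohorts
        cfg = CohortConfig(n_typical=20, n_atypical=20)
        p_exceed = norm.sf((np.log(0.3) - cfg.fd_log_mean) / cfg.fd_log_sd)
        n_cohorts, n = 400, 40
        count = sum((simulate_cohort(cfg, seed=s)["fd"] > 0.3).sum()
                    for s in range(n_cohorts))
        total = n_cohorts * n
        se = np.sqrt(p_exceed * (1 - p_exceed) / total)
        assert abs(count / total - p_exceed) < 4 * se


class TestShiftNetworks:
    def test_zero_magnitude_is_identity(self, small_geometry):
        _, _, geo, template = small_geometry
        labels, realized = shift_networks(template, np.zeros(5), geo, seed=0)
        assert np.array_equal(labels, template)
        assert (realized == 0).all()

    def test_relabeled_parcels_within_budget(self, small_geometry):
        # brute-force geodesic check: every relabeled parcel lies within the
        # configured magnitude of the shifted network's reference territory
        _, _, geo, template = small_geometry
        m = 60.0
        mags = np.zeros(5)
        mags[1] = m
        labels, _ = shift_networks(template, mags, geo, seed=3)
        changed = np.flatnonzero(labels != template)
        assert changed.size > 0
        D = geo.distance_matrix
        ref_set = np.flatnonzero(template == 2)
        comp = np.flatnonzero(template != 2)
        for p in changed:
            if labels[p] == 2:  # annexed into the shifted network
                assert D[p, ref_set].min() <= m + 1e-9
            else:  # released from it
                assert template[p] == 2
                assert D[p, comp].min() <= m + 1e-9

    def test_msd_monotone_in_magnitude(self, small_geometry):
        _, _, geo, template = small_geometry
        ref_set = np.flatnonzero(template == 1)
        for seed in range(3):
            prev = -1.0
            for m in (0.0, 30.0, 60.0, 90.0):
                mags = np.zeros(5)
                mags[0] = m
                labels, _ = shift_networks(template, mags, geo, seed=seed)
                cur = mean_surface_distance(ref_set, np.flatnonzero(labels == 1), geo)
                assert cur >= prev - 1e-12
                prev = cur

    def test_magnitude_beyond_territory_diameter_raises(self, small_geometry):
        _, _, geo, template = small_geometry
        mags = np.full(5, 1e4)
        with pytest.raises(ValueError, match="vanish"):
            shift_networks(template, mags, geo, seed=0)

    def test_all_networks_survive_shifting(self, small_geometry):
        _, _, geo, template = small_geometry
        for seed in range(5):
            labels, _ = shift_networks(template, np.full(5, 60.0), geo, seed=seed)
            assert set(np.unique(labels)) == set(range(1, 6))

    def test_negative_magnitude_rejected(self, small_geometry):
        _, _, geo, template = small_geometry
        with pytest.raises(ValueError):
            shift_networks(template, np.full(5, -1.0), geo, seed=0)


class TestTimeSeries:
    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            simulate_subject_timeseries(np.ones(5, dtype=int), 5, 0.5, seed=0)

    def test_noiseless_within_correlation_is_one(self):
        labels = np.repeat([1, 2], 5)
        ts = simulate_subject_timeseries(labels, 100, 0.5, seed=0, noise_sd=0.0)
        r = np.corrcoef(ts.values)
        assert np.allclose(r[:5, :5], 1.0, atol=1e-10)

    def test_cross_network_correlation_near_zero(self):
        labels = np.repeat([1, 2], 10)
        ts = simulate_subject_timeseries(labels, 20000, 0.9, seed=1,
                                         global_coupling=0.0)
        r = np.corrcoef(ts.values)
        assert abs(r[:10, 10:].mean()) < 0.02

    def test_within_correlation_matches_mixing_formula(self):
        # Monte-Carlo against r = 1 / (1 + sigma^2); target r = 0.5
        labels = np.repeat(np.arange(1, 5), 10)
        ts = simulate_subject_timeseries(labels, 10000, 0.5, seed=2)
        r = np.corrcoef(ts.values)
        within = []
        for k in range(4):
            block = r[10 * k:10 * (k + 1), 10 * k:10 * (k + 1)]
            within += list(block[np.triu_indices(10, k=1)])
        assert np.mean(within) == pytest.approx(0.5, abs=0.03)

    def test_amplitude_does_not_change_correlations(self):
        labels = np.repeat([1, 2], 5)
        a = simulate_subject_timeseries(labels, 200, 0.5, seed=3, amplitude=1.0)
        b = simulate_subject_timeseries(labels, 200, 0.5, seed=3, amplitude=2.5)
        assert np.allclose(np.corrcoef(a.values), np.corrcoef(b.values))


class TestDataset:
    def test_deterministic(self):
        sc = tiny_scenario(n_per_group=2)
        a = simulate_dataset(sc, seed=9)
        b = simulate_dataset(sc, seed=9)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        pd.testing.assert_frame_equal(a.ground_truth.subject_labels,
                                      b.ground_truth.subject_labels)
        sid = a.cohort["id"].iloc[0]
        assert np.array_equal(a.timeseries[sid].values, b.timeseries[sid].values)

    def test_effect_injection(self):
        # configured group difference must appear in realized shifts of the
        # increased networks in every replicate
        sc = tiny_scenario(n_per_group=6)
        for seed in (1, 2, 3):
            ds = simulate_dataset(sc, seed=seed)
            grp = ds.cohort.set_index("id")["group"]
            inc = list(ds.ground_truth.realized_shift.columns[:4])
            means = ds.ground_truth.realized_shift[inc].mean(axis=1).groupby(grp).mean()
            assert means["atypical"] > means["typical"]

    def test_networks_nonempty_per_subject(self, tiny_dataset):
        labs = tiny_dataset.ground_truth.subject_labels.to_numpy()
        for row in labs:
            assert set(np.unique(row)) == set(range(1, 6))

    def test_ground_truth_block_structure_noiseless(self):
        # zero noise, zero shift: FC is exactly block structured by network
        sc = tiny_scenario(n_per_group=2)
        sc.shift = dataclasses.replace(
            sc.shift, typical_base=0.0, atypical_increase=0.0, decrease_typical=0.0,
            decrease_atypical=0.0, age_slope=0.0, subject_sd=0.0)
        sc.timeseries = dataclasses.replace(sc.timeseries, global_coupling=0.0)
        ds = simulate_dataset(sc, seed=4)
        sid = ds.cohort["id"].iloc[0]
        labels = ds.ground_truth.subject_labels.loc[sid].to_numpy()
        assert np.array_equal(labels, ds.template_labels)
        ts = simulate_subject_timeseries(labels, 200, 0.5, seed=5, noise_sd=0.0)
        r = np.corrcoef(ts.values)
        same = labels[:, None] == labels[None, :]
        assert np.allclose(r[same], 1.0, atol=1e-10)
        assert np.abs(r[~same]).max() < 0.35  # finite-sample correlation of independent latents
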