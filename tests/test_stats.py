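"""GLM contrasts, TFCE, permutation correction, FDR, spin tests, severity/age."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as sps

from idioconn.stats import (DesignMatrix, age_effect, build_design,
                            cohens_d, entropy_contrast, fdr_bh, glm_contrast,
                            permutation_correct, reference_bootstrap,
                            severity_correlation, spin_test, tfce)

from conftest import random_geodesic_graph


def simple_cohort(n_per=10, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "group": ["typical"] * n_per + ["atypical"] * n_per,
        "site": rng.choice(["a", "b"], size=n),
        "age": rng.uniform(8, 40, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "fd": rng.uniform(0, 0.2, size=n),
        "severity": np.nan,
    })


def group_only_design(groups):
    g = np.asarray(groups, dtype=float)
    X = np.column_stack([np.ones(g.size), g])
    return DesignMatrix(X=X, columns=["intercept", "group"],
                        contrast=np.array([0.0, 1.0]))


class TestGlmContrast:
    def test_matches_pooled_two_sample_t(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        d = group_only_design([0, 0, 0, 1, 1, 1])
        t, p = glm_contrast(y, d)
        assert t == pytest.approx(3.674, abs=1e-3)  # diff 3, se sqrt(2/3)
        t_ref, p_ref = sps.ttest_ind(y[3:], y[:3])
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_pooled_t_identity_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.standard_normal(24)
            g = np.repeat([0, 1], 12)
            t, _ = glm_contrast(y, group_only_design(g))
            t_ref = sps.ttest_ind(y[g == 1], y[g == 0]).statistic
            assert t == pytest.approx(t_ref, abs=1e-10)

    def test_orthogonal_outcome_gives_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        d = group_only_design([0, 0, 1, 1])
        t, _ = glm_contrast(y, d)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_collinear_covariate_rejected(self):
        g = np.repeat([0.0, 1.0], 5)
        X = np.column_stack([np.ones(10), g, g])
        with pytest.raises(ValueError, match="collinear"):
            DesignMatrix(X=X, columns=["intercept", "group", "dup"],
                         contrast=np.array([0.0, 1.0, 0.0]))

    def test_build_design_full_rank_with_covariates(self):
        cohort = simple_cohort()
        d = build_design(cohort)
        assert d.X.shape[0] == 20
        assert d.columns[:2] == ["intercept", "group"]
        assert np.linalg.matrix_rank(d.X) == d.X.shape[1]


class TestTfce:
    @staticmethod
    def _oracle(t, adjacency, E, H, dh):
        """Independent per-threshold BFS implementation (both tails)."""
        import networkx as nx

        out = np.zeros_like(t)
        G = nx.from_scipy_sparse_array(sp.csr_matrix(adjacency))
        for sgn in (1.0, -1.0):
            side = np.where(sgn * t > 0, sgn * t, 0.0)
            if side.max() <= 0:
                continue
            n_steps = int(side.max() / dh)
            for j in range(1, n_steps + 1):
                h = j * dh
                active = set(np.flatnonzero(side >= h).tolist())
                sub = G.subgraph(active)
                for comp in nx.connected_components(sub):
                    for p in comp:
                        out[p] += len(comp) ** E * h ** H * dh
        return out

    def test_isolated_parcel_single_step(self):
        # one suprathreshold parcel, one threshold step: 1^E * h0^H * dh
        t = np.zeros(5)
        t[2] = 3.0
        adj = sp.csr_matrix(np.diag(np.ones(4), 1) + np.diag(np.ones(4), -1))
        out = tfce(t, adj, E=0.5, H=2.0, dh=3.0)
        assert out[2] == pytest.approx(1.0**0.5 * 3.0**2 * 3.0)
        assert out[[0, 1, 3, 4]].sum() == 0

    def test_zero_map_stays_zero(self):
        adj = sp.eye(6, k=1) + sp.eye(6, k=-1)
        assert np.allclose(tfce(np.zeros(6), adj), 0.0)

    def test_height_integration_limit(self):
        # E=0, H=1, fine dh: TFCE(p) -> integral of h dh = t^2/2 on an
        # isolated parcel
        t = np.zeros(3)
        t[1] = 2.0
        adj = sp.csr_matrix((3, 3))
        out = tfce(t, adj, E=0.0, H=1.0, n_steps=20000)
        assert out[1] == pytest.approx(2.0**2 / 2, rel=1e-3)

    def test_matches_bfs_oracle_on_random_maps(self):
        rng = np.random.default_rng(2)
        g = random_geodesic_graph(30, rng)
        adj = (g.weights > 0).astype(float)
        for seed in range(3):
            t = np.random.default_rng(seed).standard_normal(30) * 2
            dh = np.abs(t).max() / 40
            ours = tfce(t, adj, E=0.5, H=2.0, dh=dh)
            oracle = self._oracle(t, adj, 0.5, 2.0, dh)
            assert np.allclose(ours, oracle, rtol=1e-10)

    def test_numba_and_scipy_paths_agree(self):
        from idioconn._tfce import _tfce_side_scipy, edges_from_adjacency, \
            _tfce_side_kernel

        rng = np.random.default_rng(3)
        g = random_geodesic_graph(25, rng)
        adj = (g.weights > 0).astype(float)
        t = np.abs(rng.standard_normal(25))
        eu, ev = edges_from_adjacency(adj)
        a = _tfce_side_kernel(t, eu, ev, 0.5, 2.0, t.max() / 30)
        b = _tfce_side_scipy(t, adj, 0.5, 2.0, t.max() / 30)
        assert np.allclose(a, b, rtol=1e-10)


class TestPermutationCorrect:
    def _setup(self, n_per=8, P=12, seed=0):
        rng = np.random.default_rng(seed)
        cohort = simple_cohort(n_per, seed=seed)
        design = build_design(cohort)
        g = random_geodesic_graph(P, rng)
        return rng, design, (g.weights > 0).astype(float)

    def test_constant_outcome_p_is_one(self):
        _, design, adj = self._setup()
        Y = np.ones((16, 12))  # identical under every permutation
        with pytest.warns(UserWarning):
            out = permutation_correct(Y, design, adj, n_perm=99, seed=0)
        assert (out.p_corr == 1.0).all()

    def test_lower_bound_attained_under_strong_effect(self):
        rng, design, adj = self._setup(seed=1)
        group = design.X[:, design.group_index]
        Y = rng.standard_normal((16, 12)) * 0.05 + group[:, None] * 10.0
        with pytest.warns(UserWarning):
            out = permutation_correct(Y, design, adj, n_perm=99, seed=0)
        assert out.p_corr.min() == pytest.approx(1 / 100)
        assert (out.p_corr >= 1 / 100).all()

    def test_reproducible_given_seed(self):
        rng, design, adj = self._setup(seed=2)
        Y = rng.standard_normal((16, 12))
        a = permutation_correct(Y, design, adj, n_perm=120, seed=5)
        b = permutation_correct(Y, design, adj, n_perm=120, seed=5)
        assert np.array_equal(a.p_corr, b.p_corr)


class TestFdrBh:
    def test_textbook_example(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.37])[0] == pytest.approx(0.37)

    def test_matches_definitional_oracle(self):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = p.size
            order = np.argsort(p, kind="stable")
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.uniform(0, 1, size=rng.integers(2, 30))
            assert np.allclose(fdr_bh(p), oracle(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    def test_monotone_bounded_and_dominating(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 20)
        adj = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in order stats
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()


class TestCohensD:
    def test_unit_pooled_sd_example(self):
        y = np.array([1.0, 2, 3, 4, 5, 6])
        g = np.array([0, 0, 0, 1, 1, 1])
        assert cohens_d(y, g) == pytest.approx(3.0)

    def test_identical_groups_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))

    def test_sign_flips_with_labels(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(20)
        g = np.repeat([0, 1], 10)
        assert cohens_d(y, g) == pytest.approx(-cohens_d(y, 1 - g))


class TestSpinTest:
    def _centroids(self, P=60, seed=0):
        x = np.random.default_rng(seed).standard_normal((P, 3))
        return x / np.linalg.norm(x, axis=1, keepdims=True)

    def test_self_correlation(self):
        cent = self._centroids()
        a = np.random.default_rng(1).standard_normal(60)
        out = spin_test(a, a, cent, n_rot=199, seed=0)
        assert out.observed_r == pytest.approx(1.0)
        assert out.p_spin == pytest.approx(1 / 200)

    def test_constant_map_rejected(self):
        cent = self._centroids()
        with pytest.raises(ValueError):
            spin_test(np.ones(60), np.arange(60.0), cent)

    def test_reproducible(self):
        cent = self._centroids(seed=2)
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((2, 60))
        x = spin_test(a, b, cent, n_rot=99, seed=7)
        y = spin_test(a, b, cent, n_rot=99, seed=7)
        assert np.array_equal(x.null_r, y.null_r)
        assert x.p_spin == y.p_spin

    def test_smooth_maps_spin_conservative_vs_parametric(self):
        # two independent but spatially smooth maps: the parametric p is
        # anticonservative, the spin p is not
        cent = self._centroids(P=150, seed=4)
        rng = np.random.default_rng(5)
        rej_param, rej_spin = 0, 0
        n_rep = 40
        for _ in range(n_rep):
            u, v = rng.standard_normal((2, 3))
            a = cent @ u + 0.2 * rng.standard_normal(150)
            b = cent @ v + 0.2 * rng.standard_normal(150)
            r, p_param = sps.pearsonr(a, b)
            out = spin_test(a, b, cent, n_rot=99, seed=int(rng.integers(2**31)))
            rej_param += p_param < 0.05
            rej_spin += out.p_spin < 0.05
        assert rej_spin / n_rep < 0.2
        assert rej_param > rej_spin


class TestSeverityCorrelation:
    def test_exact_linear_recovery(self):
        cohort = simple_cohort(12, seed=6)
        vals = pd.DataFrame({"net1": np.random.default_rng(7).uniform(0, 1, 24)})
        atyp = cohort["group"] == "atypical"
        cohort.loc[atyp, "severity"] = 2 + 3 * vals.loc[atyp.to_numpy(), "net1"]
        # strip covariate influence by making covariates constant
        cohort["site"] = "a"
        cohort["sex"] = "M"
        cohort["age"] = 20.0
        out = severity_correlation(vals, cohort, covariates=())
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_uncorrelated_covariates_match_plain_pearson(self):
        rng = np.random.default_rng(8)
        cohort = simple_cohort(30, seed=8)
        vals = pd.DataFrame({"net1": rng.uniform(0, 1, 60)})
        atyp = (cohort["group"] == "atypical").to_numpy()
        cohort.loc[atyp, "severity"] = rng.uniform(1, 10, atyp.sum())
        out = severity_correlation(vals, cohort)
        v = vals["net1"].to_numpy()
        mu, sd = v[~atyp].mean(), v[~atyp].std(ddof=1)
        plain = sps.pearsonr((v[atyp] - mu) / sd,
                             cohort.loc[atyp, "severity"]).statistic
        assert out["r"].iloc[0] == pytest.approx(plain, abs=0.25)

    def test_independent_severity_mean_r_near_zero(self):
        rs = []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            cohort = simple_cohort(15, seed=seed)
            atyp = (cohort["group"] == "atypical").to_numpy()
            cohort.loc[atyp, "severity"] = rng.uniform(1, 10, atyp.sum())
            vals = pd.DataFrame({"net1": rng.uniform(0, 1, 30)})
            rs.append(severity_correlation(vals, cohort)["r"].iloc[0])
        assert abs(np.mean(rs)) < 0.15

    def test_too_few_atypical_rejected(self):
        cohort = simple_cohort(2)
        with pytest.raises(ValueError):
            severity_correlation(pd.DataFrame({"net1": np.zeros(4)}), cohort)


class TestAgeEffect:
    def test_perfect_fit_flagged(self):
        cohort = simple_cohort(10, seed=9)
        y = 2.0 * cohort["age"].to_numpy()
        out = age_effect(y, cohort, covariates=())
        assert out.exact_fit
        assert np.isinf(out.age_t)

    def test_equal_slopes_interaction_centred_on_zero(self):
        ts = []
        for seed in range(15):
            rng = np.random.default_rng(200 + seed)
            cohort = simple_cohort(20, seed=seed)
            y = 0.5 * cohort["age"].to_numpy() + rng.standard_normal(40)
            ts.append(age_effect(y, cohort).interaction_t)
        assert abs(np.mean(ts)) < 0.5
        assert np.mean([abs(t) < 2.5 for t in ts]) > 0.8

    def test_child_adult_split_is_strict(self):
        cohort = simple_cohort(10, seed=10)
        cohort.loc[0, "age"] = 18.0
        children = cohort[cohort["age"] < 18]
        adults = cohort[cohort["age"] >= 18]
        assert len(children) + len(adults) == len(cohort)
        assert 0 in adults.index


class TestEntropyContrast:
    def test_spread_group_has_higher_entropy(self):
        rng = np.random.default_rng(11)
        P, N = 40, 3
        ref = np.repeat([1, 2, 3], [15, 15, 10])
        certain = []
        for _ in range(6):
            p = np.zeros((P, N))
            p[np.arange(P), ref - 1] = 1.0
            certain.append(p)
        spread = [rng.dirichlet(np.ones(N), size=P) for _ in range(6)]
        out = entropy_contrast(certain, spread, ref, N)
        assert (out["t"] > 0).all()
        assert (out["mean_atypical"] > out["mean_typical"]).all()


class TestReferenceBootstrap:
    def test_replicates_and_determinism(self, tiny_dataset):
        from idioconn.connectome import compute_fc
        from idioconn.embedding import EmbeddingConfig, affinity, diffusion_map

        ds = tiny_dataset
        ids = ds.cohort["id"].tolist()
        cfg = EmbeddingConfig(n_components=15)
        fcs = {i: compute_fc(ds.timeseries[i]) for i in ids}
        embs = {i: diffusion_map(affinity(fcs[i]), cfg) for i in ids}
        a = reference_bootstrap(embs, fcs, ds.cohort, ds.template_labels,
                                ds.geodesic, cfg, n_boot=2, seed=3)
        b = reference_bootstrap(embs, fcs, ds.cohort, ds.template_labels,
                                ds.geodesic, cfg, n_boot=2, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["replicate"]) == {0, 1}
        assert set(a["group"]) == {"typical", "atypical"}

    def test_groups_separate_across_references(self, tiny_dataset):
        # strong injected group effect: the group-wise cortex-wide MSD
        # distributions across bootstrap references do not overlap
        from idioconn.connectome import compute_fc
        from idioconn.embedding import EmbeddingConfig, affinity, diffusion_map

        ds = tiny_dataset
        ids = ds.cohort["id"].tolist()
        cfg = EmbeddingConfig(n_components=15)
        fcs = {i: compute_fc(ds.timeseries[i]) for i in ids}
        embs = {i: diffusion_map(affinity(fcs[i]), cfg) for i in ids}
        out = reference_bootstrap(embs, fcs, ds.cohort, ds.template_labels,
                                  ds.geodesic, cfg, n_boot=4, seed=1)
        msd = out.pivot(index="replicate", columns="group", values="msd")
        assert msd["atypical"].min() > msd["typical"].max()

    def test_subsample_size_floor(self):
        with pytest.raises(ValueError):
            reference_bootstrap({}, {}, simple_cohort(1), np.array([1]), None,
                                fraction=0.5, n_boot=2)
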