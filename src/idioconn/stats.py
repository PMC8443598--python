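"""Inferential machinery for idiosyncrasy analyses.

General linear models with site/sex/age nuisance covariates for group
contrasts; TFCE with max-statistic permutation correction for parcel-wise
maps; Benjamini-Hochberg FDR for network-level families; Cohen's d;
spherical spin tests for spatial map correlations; severity and age
associations; and the reference-embedding bootstrap.

Group labels are permuted within acquisition site (restricted
exchangeability) because site is the dominant nuisance in multi-site
cohorts; free permutation is available via ``sites=None``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

from ._tfce import tfce_enhance

__all__ = [
    "DesignMatrix", "build_design", "glm_contrast", "tfce", "GroupStatMap",
    "permutation_correct", "fdr_bh", "cohens_d", "SpinNull", "spin_test",
    "severity_correlation", "AgeEffect", "age_effect", "reference_bootstrap",
    "entropy_contrast",
]


# ---------------------------------------------------------------------------
# design matrices and OLS


@dataclasses.dataclass
class DesignMatrix:
    """OLS design with an intercept, a 0/1 group column and covariates."""

    X: np.ndarray  # (n, q)
    columns: list
    contrast: np.ndarray  # (q,)
    sites: np.ndarray | None = None  # site labels for restricted permutation

    def __post_init__(self) -> None:
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            culprits = _collinear_columns(self.X, self.columns)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")

    @property
    def group_index(self) -> int:
        return int(np.flatnonzero(self.contrast)[0])


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list:
    bad = []
    for j in range(x.shape[1]):
        rest = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(x):
            bad.append(names[j])
    return bad


def build_design(cohort: pd.DataFrame, covariates: Sequence[str] = ("site", "sex", "age"),
                 extra: pd.DataFrame | None = None) -> DesignMatrix:
    """Intercept + group (0 = typical, 1 = atypical) + nuisance covariates.

    Site and sex are one-hot coded with the first level dropped; extra
    numeric covariates (e.g., surface area) can be appended.
    """
    n = len(cohort)
    cols: list = ["intercept", "group"]
    mats = [np.ones(n), (cohort["group"] == "atypical").to_numpy(dtype=float)]
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"cohort lacks covariate column '{cov}'")
        v = cohort[cov]
        if v.dtype.kind in "OUSb" or cov in ("site", "sex"):
            levels = sorted(v.unique())
            for lev in levels[1:]:
                cols.append(f"{cov}[{lev}]")
                mats.append((v == lev).to_numpy(dtype=float))
        else:
            cols.append(cov)
            mats.append(v.to_numpy(dtype=float))
    if extra is not None:
        for c in extra.columns:
            cols.append(str(c))
            mats.append(extra[c].to_numpy(dtype=float))
    X = np.column_stack(mats)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    sites = cohort["site"].to_numpy() if "site" in cohort.columns else None
    return DesignMatrix(X=X, columns=cols, contrast=contrast, sites=sites)


def _ols_t(y: np.ndarray, X: np.ndarray, contrast: np.ndarray):
    """Closed-form OLS t and two-sided p for one contrast.

    A numerically perfect fit is reported as t = +-inf, p = 0 (exact-fit
    condition).
    """
    n, q = X.shape
    if n <= q:
        raise ValueError("need more subjects than design columns")
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    resid = y - X @ beta
    rank = np.linalg.matrix_rank(X)
    df = n - rank
    rss = float(resid @ resid)
    sigma2 = rss / df
    xtx_inv = pinv @ pinv.T
    cvar = float(contrast @ xtx_inv @ contrast)
    eff = float(contrast @ beta)
    scale = max(1.0, float(y @ y))
    if sigma2 * cvar <= 1e-24 * scale:
        return np.inf * np.sign(eff) if eff != 0 else 0.0, 0.0 if eff != 0 else 1.0
    t = eff / np.sqrt(sigma2 * cvar)
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def glm_contrast(y: np.ndarray, design: DesignMatrix,
                 contrast: np.ndarray | None = None):
    """OLS group contrast: t statistic and two-sided Student p."""
    c = design.contrast if contrast is None else np.asarray(contrast, dtype=float)
    return _ols_t(np.asarray(y, dtype=float), design.X, c)


def _batch_tmap(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """t statistics of one contrast for many outcomes sharing the design."""
    n, q = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (q, P)
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / df
    cvar = float(contrast @ (pinv @ pinv.T) @ contrast)
    se = np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
    eff = contrast @ beta
    t = eff / se
    return _exact_fit_guard(t, eff, sigma2, Y)


def _exact_fit_guard(t, eff, sigma2, Y):
    """Numerically perfect fits: zero effect -> t = 0, else t = +-inf."""
    scale = np.maximum((Y**2).mean(axis=0), 1e-300)
    exact = sigma2 < 1e-24 * scale
    if np.any(exact):
        t = t.copy()
        zero = np.abs(eff) <= np.sqrt(1e-24 * scale)
        t[exact & zero] = 0.0
        t[exact & ~zero] = np.sign(eff[exact & ~zero]) * np.inf
    return t


def _batch_tmap_local(Y: np.ndarray, X: np.ndarray, local: np.ndarray,
                      contrast_index: int) -> np.ndarray:
    """t map when each parcel's design has its own local covariate columns.

    ``local`` has shape (n, P, L); parcel p is fit with [X | local[:, p, :]].
    """
    n, P = Y.shape
    q = X.shape[1]
    L = local.shape[2]
    Xb = np.empty((P, n, q + L))
    Xb[:, :, :q] = X[None, :, :]
    Xb[:, :, q:] = np.transpose(local, (1, 0, 2))
    xtx = np.einsum("pnq,pnr->pqr", Xb, Xb)
    xty = np.einsum("pnq,pn->pq", Xb, Y.T[:, :].reshape(P, n))
    xtx_inv = np.linalg.pinv(xtx)
    beta = np.einsum("pqr,pr->pq", xtx_inv, xty)
    fitted = np.einsum("pnq,pq->pn", Xb, beta)
    resid = Y.T - fitted
    df = n - (q + L)
    sigma2 = (resid**2).sum(axis=1) / df
    cvar = xtx_inv[:, contrast_index, contrast_index]
    se = np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
    eff = beta[:, contrast_index]
    return _exact_fit_guard(eff / se, eff, sigma2, Y)


# ---------------------------------------------------------------------------
# TFCE + permutation correction


def tfce(t_map: np.ndarray, adjacency, E: float = 0.5, H: float = 2.0,
         dh: float | None = None, n_steps: int = 100) -> np.ndarray:
    """Threshold-free cluster enhancement of a (signed) statistic map."""
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    return tfce_enhance(np.asarray(t_map, dtype=float), adjacency,
                        e_exp=E, h_exp=H, dh=dh, n_steps=n_steps)


@dataclasses.dataclass
class GroupStatMap:
    """Parcel-wise contrast with TFCE + max-statistic permutation correction."""

    t: np.ndarray
    tfce: np.ndarray
    p_corr: np.ndarray
    increase_mask: np.ndarray
    decrease_mask: np.ndarray
    n_perm: int
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.increase_mask.sum() + self.decrease_mask.sum())


def _permute_within(labels: np.ndarray, sites: np.ndarray | None,
                    rng: np.random.Generator) -> np.ndarray:
    perm = np.arange(labels.size)
    if sites is None:
        rng.shuffle(perm)
        return labels[perm]
    out = labels.copy()
    for s in np.unique(sites):
        idx = np.flatnonzero(sites == s)
        out[idx] = labels[idx[rng.permutation(idx.size)]]
    return out


def permutation_correct(Y: np.ndarray, design: DesignMatrix, adjacency,
                        n_perm: int = 1000, seed: int = 0,
                        local_covariates: np.ndarray | None = None,
                        alpha: float = 0.05, E: float = 0.5, H: float = 2.0,
                        n_steps: int = 100) -> GroupStatMap:
    """Family-wise corrected parcel-wise group contrast.

    The group column is permuted (within site when the design carries site
    labels), the t-map and its TFCE enhancement recomputed each time, and
    p_corr(p) = (1 + #{null max-TFCE >= observed TFCE(p)}) / (n_perm + 1).
    ``local_covariates`` (n, P, L) adds per-parcel covariate columns (e.g.
    each subject's SD and DD at that parcel) to that parcel's design.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value floor",
                      stacklevel=2)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    gi = design.group_index

    def tmap(labels: np.ndarray) -> np.ndarray:
        X = design.X.copy()
        X[:, gi] = labels
        if local_covariates is None:
            t = _batch_tmap(Y, X, design.contrast)
        else:
            t = _batch_tmap_local(Y, X, local_covariates, gi)
        # exact fits carry infinite t; keep TFCE finite
        return np.clip(t, -1e6, 1e6)

    group = design.X[:, gi].copy()
    t_obs = tmap(group)
    enh_obs = tfce(t_obs, adjacency, E=E, H=H, n_steps=n_steps)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        lab = _permute_within(group, design.sites, rng)
        enh = tfce(tmap(lab), adjacency, E=E, H=H, n_steps=n_steps)
        null_max[b] = enh.max()
    p_corr = (1 + (null_max[None, :] >= enh_obs[:, None]).sum(axis=1)) / (n_perm + 1)
    inc = (p_corr < alpha) & (t_obs > 0)
    dec = (p_corr < alpha) & (t_obs < 0)
    return GroupStatMap(t=t_obs, tfce=enh_obs, p_corr=p_corr,
                        increase_mask=inc, decrease_mask=dec,
                        n_perm=n_perm, alpha=alpha)


# ---------------------------------------------------------------------------
# simple statistics


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(y: np.ndarray, groups: np.ndarray) -> float:
    """Cohen's d (atypical minus typical) with the pooled n-1 SD."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups)
    if g.dtype.kind in "OUS":
        g = (g == "atypical").astype(int)
    y0, y1 = y[g == 0], y[g == 1]
    if y0.size < 2 or y1.size < 2:
        raise ValueError("need at least two observations per group")
    s2 = ((y0.size - 1) * y0.var(ddof=1) + (y1.size - 1) * y1.var(ddof=1)) / (y0.size + y1.size - 2)
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((y1.mean() - y0.mean()) / np.sqrt(s2))


# ---------------------------------------------------------------------------
# spin tests


@dataclasses.dataclass
class SpinNull:
    observed_r: float
    null_r: np.ndarray
    p_spin: float


def spin_test(map_a: np.ndarray, map_b: np.ndarray, centroids: np.ndarray,
              n_rot: int = 1000, seed: int = 0) -> SpinNull:
    """Spatial correlation with a spherical-rotation null.

    The observed statistic is the Pearson correlation of the two parcel
    maps. Null maps are built by applying uniform random 3-D rotations to
    the parcel centroids and reassigning each parcel the value of the
    nearest rotated parcel (duplicates allowed, as in standard parcel-level
    spin practice); p is two-sided on |r|.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("spin test is undefined for constant maps")
    obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_rot, random_state=rng)
    tree = cKDTree(centroids)
    null = np.empty(n_rot)
    for i, rot in enumerate(rots):
        rotated = rot.apply(centroids)
        idx = tree.query(rotated, k=1)[1]
        null[i] = np.corrcoef(a[idx], b)[0, 1]
    p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_rot + 1)
    return SpinNull(observed_r=obs, null_r=null, p_spin=float(p))


# ---------------------------------------------------------------------------
# severity, age, entropy


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covs])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def severity_correlation(values: pd.DataFrame, cohort: pd.DataFrame,
                         covariates: Sequence[str] = ("age", "sex", "site")) -> pd.DataFrame:
    """Correlation of per-network descriptors with symptom severity.

    Each column of ``values`` (subjects x networks, indexed like the
    cohort) is z-scored with respect to the typical group, the covariates
    are regressed out among atypical subjects, and the residuals are
    correlated (Pearson) with the severity score; p-values are BH-FDR
    corrected across networks.
    """
    atyp = (cohort["group"] == "atypical").to_numpy()
    if atyp.sum() < 4:
        raise ValueError("need at least 4 atypical subjects")
    sev = cohort.loc[atyp, "severity"].to_numpy(dtype=float)
    cov_design = build_design(cohort, covariates=covariates)
    covs = cov_design.X[:, 2:][atyp]  # drop intercept and group columns

    rows = []
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        mu, sd = v[~atyp].mean(), v[~atyp].std(ddof=1)
        vz = (v - mu) / (sd if sd > 0 else 1.0)
        resid = _residualize(vz[atyp], covs)
        r, p = sps.pearsonr(resid, sev)
        rows.append({"network": col, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out


@dataclasses.dataclass
class AgeEffect:
    age_t: float
    age_p: float
    interaction_t: float
    interaction_p: float
    exact_fit: bool


def age_effect(y: np.ndarray, cohort: pd.DataFrame,
               covariates: Sequence[str] = ("site", "sex")) -> AgeEffect:
    """Age slope and group-by-age interaction of a descriptor.

    Fits y ~ intercept + group + age + group:age + covariates and reports
    the t statistics of the age and interaction terms. A perfect fit is
    flagged (t reported as +-inf).
    """
    base = build_design(cohort, covariates=covariates)
    age = cohort["age"].to_numpy(dtype=float)
    group = base.X[:, base.group_index]
    X = np.column_stack([base.X, age - age.mean(), group * (age - age.mean())])
    cols = base.columns + ["age", "group:age"]
    q = X.shape[1]
    c_age = np.zeros(q)
    c_age[q - 2] = 1.0
    c_int = np.zeros(q)
    c_int[q - 1] = 1.0
    d = DesignMatrix(X=X, columns=cols, contrast=c_age, sites=base.sites)
    t_age, p_age = _ols_t(np.asarray(y, dtype=float), d.X, c_age)
    t_int, p_int = _ols_t(np.asarray(y, dtype=float), d.X, c_int)
    return AgeEffect(age_t=t_age, age_p=p_age, interaction_t=t_int,
                     interaction_p=p_int, exact_fit=bool(np.isinf(t_age) or np.isinf(t_int)))


def entropy_contrast(posteriors_typical, posteriors_atypical,
                     reference_labels: np.ndarray, n_networks: int) -> pd.DataFrame:
    """Two-sample t-tests of group entropy maps within each reference network.

    Group-wise entropy maps are computed from the averaged probability maps
    of each group; within every reference network the parcel-wise entropy
    values of the two groups are compared with a two-sample t-test, with
    Cohen's d reported alongside.
    """
    from .idiosyncrasy import network_entropy

    h_typ = network_entropy(posteriors_typical)
    h_atyp = network_entropy(posteriors_atypical)
    ref = np.asarray(reference_labels)
    rows = []
    for k in range(1, n_networks + 1):
        m = ref == k
        t, p = sps.ttest_ind(h_atyp[m], h_typ[m])
        pooled = np.concatenate([np.zeros(m.sum(), dtype=int), np.ones(m.sum(), dtype=int)])
        d = cohens_d(np.concatenate([h_typ[m], h_atyp[m]]), pooled)
        rows.append({"network": k, "t": float(t), "p": float(p), "cohens_d": d,
                     "mean_typical": float(h_typ[m].mean()),
                     "mean_atypical": float(h_atyp[m].mean())})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# reference bootstrap


def reference_bootstrap(embeddings: Mapping[str, object], fcs: Mapping[str, object],
                        cohort: pd.DataFrame, template_labels: np.ndarray,
                        geo, cfg=None, fraction: float = 0.5, n_boot: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """Robustness of descriptors to the choice of reference embedding.

    Each replicate rebuilds the reference from the mean connectivity of a
    random half of the subjects (floor(fraction * n), without replacement),
    re-aligns and re-clusters *all* subjects against it, and records the
    group-wise cortex-wide mean Dice, Jaccard and MSD.
    """
    from .clustering import cluster_individual, fit_reference_gmm
    from .connectome import group_average
    from .embedding import EmbeddingConfig, build_reference, change_of_basis
    from .idiosyncrasy import network_size, network_summaries, cortexwide_summary

    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    cfg = cfg or EmbeddingConfig()
    ids = cohort["id"].tolist()
    n_sub = int(np.floor(fraction * len(ids)))
    if n_sub < 2:
        raise ValueError("subsample too small to build a reference embedding")
    rng = np.random.default_rng(seed)
    n_net = int(np.max(template_labels))
    rows = []
    for b in range(n_boot):
        chosen = rng.choice(len(ids), size=n_sub, replace=False)
        mean_fc = group_average([fcs[ids[i]] for i in chosen])
        ref_emb = build_reference(mean_fc, cfg)
        params, ref_assign = fit_reference_gmm(ref_emb, template_labels)
        sizes = network_size(ref_assign, n_net)
        sizes = np.where(sizes > 0, sizes, 1)
        for sid in ids:
            _, aligned = change_of_basis(embeddings[sid], ref_emb)
            assign = cluster_individual(aligned, params, source=sid)
            summ = network_summaries(assign, ref_assign, geo, n_net)
            grp = cohort.loc[cohort["id"] == sid, "group"].iloc[0]
            rows.append({
                "replicate": b, "id": sid, "group": grp,
                "dice": cortexwide_summary(np.nan_to_num(summ["dice"]), sizes),
                "jaccard": cortexwide_summary(np.nan_to_num(summ["jaccard"]), sizes),
                "msd": cortexwide_summary(np.nan_to_num(summ["msd"]), sizes),
            })
    per_subject = pd.DataFrame(rows)
    return (per_subject.groupby(["replicate", "group"])[["dice", "jaccard", "msd"]]
            .mean().reset_index())
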