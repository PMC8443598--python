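"""Model/Results facade over the idiosyncrasy pipeline.

`IdiosyncrasyModel` holds a cohort's parcel time series together with the
cortical geometry and network template; `fit()` executes the full analysis
— QC, connectivity, reference embedding, alignment, network clustering,
idiosyncrasy descriptors and group statistics — and returns an
`IdiosyncrasyResults` carrying the estimates, corrected p-values and
summary tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as iio
from .centrality import CentralityContrast, centrality_contrast, degree_centrality, \
    eigenvector_centrality
from .clustering import GMMParameters, NetworkAssignment, cluster_individual, \
    fit_reference_gmm
from .connectome import compute_fc, group_average, qc_filter
from .embedding import Embedding, affinity, build_reference, change_of_basis, \
    diffusion_map
from .idiosyncrasy import GeodesicGraph, GradientStratification, cortexwide_summary, \
    diffusion_distance, gradient_stratification, network_size, network_summaries, \
    surface_distance
from .stats import GroupStatMap, age_effect, build_design, cohens_d, \
    entropy_contrast, fdr_bh, glm_contrast, permutation_correct, severity_correlation, \
    spin_test

logger = logging.getLogger(__name__)

__all__ = ["IdiosyncrasyModel", "IdiosyncrasyResults", "run_pipeline"]

_DESCRIPTORS = ("msd", "dice", "jaccard", "size", "mean_sd", "mean_dd")


@dataclasses.dataclass
class IdiosyncrasyResults:
    """Fitted idiosyncrasy analysis of one cohort."""

    cohort: pd.DataFrame
    reference_embedding: Embedding
    reference_assignment: NetworkAssignment
    reference_gmm: GMMParameters
    subject_assignments: dict
    sd_maps: pd.DataFrame  # subjects x parcels
    dd_maps: pd.DataFrame
    network_values: dict  # descriptor -> subjects x networks (+ 'cortex')
    network_table: pd.DataFrame  # long: descriptor, network, t, p, p_fdr, d
    entropy_table: pd.DataFrame
    severity_table: pd.DataFrame | None
    age_table: pd.DataFrame
    sd_statmap: GroupStatMap | None
    dd_statmap: GroupStatMap | None
    dc_contrast: CentralityContrast | None
    ec_contrast: CentralityContrast | None
    spin_tables: dict
    gradient_sd: GradientStratification
    gradient_dd: GradientStratification
    config_hash: str
    seed: int
    n_perm: int
    alignment_residuals: pd.Series | None = None

    def summary(self) -> str:
        """Human-readable account of the main group findings."""
        lines = ["Idiosyncrasy analysis summary",
                 "=" * 64,
                 f"subjects: {len(self.cohort)} "
                 f"({(self.cohort['group'] == 'typical').sum()} typical / "
                 f"{(self.cohort['group'] == 'atypical').sum()} atypical), "
                 f"parcels: {self.sd_maps.shape[1]}, "
                 f"networks: {self.reference_assignment.n_networks}",
                 f"config hash: {self.config_hash}, seed: {self.seed}, "
                 f"n_perm: {self.n_perm}",
                 "",
                 "Network-level group contrasts (atypical - typical):"]
        tab = self.network_table[self.network_table["descriptor"].isin(["msd", "mean_dd"])]
        lines.append(tab.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        if self.sd_statmap is not None:
            lines += ["",
                      f"parcel-wise SD: {self.sd_statmap.n_significant} significant parcels "
                      f"(TFCE, FWE {self.sd_statmap.alpha})",
                      f"parcel-wise DD: {self.dd_statmap.n_significant} significant parcels"]
        if self.dc_contrast is not None:
            lines += ["",
                      "degree-centrality contrast: "
                      f"{self.dc_contrast.n_significant_before} significant parcels before / "
                      f"{self.dc_contrast.n_significant_after} after controlling for SD+DD"]
        if self.severity_table is not None:
            lines += ["", "severity associations (mean DD):",
                      self.severity_table.to_string(index=False,
                                                    float_format=lambda v: f"{v: .4f}")]
        return "\n".join(lines)

    def plot_summary(self, path=None):
        """Two-panel overview: per-network MSD group contrast and mean
        idiosyncrasy along the principal gradient. Returns the figure."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        msd = self.network_table[
            (self.network_table["descriptor"] == "msd")
            & (self.network_table["network"] != "cortex")]
        colors = ["firebrick" if t > 0 else "steelblue" for t in msd["t"]]
        ax1.bar(msd["network"], msd["t"], color=colors)
        ax1.axhline(0, color="k", lw=0.8)
        ax1.set_ylabel("group t (atypical - typical)")
        ax1.set_title("network MSD contrast")
        ax1.tick_params(axis="x", rotation=45)
        bins = np.arange(1, self.gradient_sd.bin_means.size + 1)
        ax2.plot(bins, self.gradient_sd.bin_means, "o-", label="SD")
        ax2.set_xlabel("principal-gradient bin")
        ax2.set_ylabel("mean SD (length units)")
        ax2.set_title(f"gradient trend (rho = {self.gradient_sd.spearman_rho:.2f})")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class IdiosyncrasyModel:
    """Idiosyncrasy profiling of a two-group, multi-site cohort.

    Parameters
    ----------
    timeseries : mapping id -> TimeSeriesMatrix
    cohort : DataFrame with columns id, group, site, age, sex, fd, severity
    geodesic : GeodesicGraph
        Parcel-level geodesic graph (carries parcel centroids).
    template_labels : ndarray (P,)
        Template network atlas (ids 1..N) that initializes the clustering.
    config : RunConfig, optional
    """

    def __init__(self, timeseries: Mapping, cohort: pd.DataFrame,
                 geodesic: GeodesicGraph, template_labels: np.ndarray,
                 config: "iio.RunConfig | None" = None):
        self.timeseries = dict(timeseries)
        self.cohort = cohort.reset_index(drop=True)
        self.geodesic = geodesic
        self.template_labels = np.asarray(template_labels, dtype=int)
        self.config = config or iio.RunConfig()
        missing = set(self.cohort["id"]) - set(self.timeseries)
        if missing:
            raise ValueError(f"missing time series for subject(s): {sorted(missing)[:5]}")

    @classmethod
    def from_dataset(cls, dataset, config=None) -> "IdiosyncrasyModel":
        return cls(dataset.timeseries, dataset.cohort, dataset.geodesic,
                   dataset.template_labels, config=config)

    # -- stages --------------------------------------------------------

    def _network_level_stats(self, values: dict, design, cohort) -> pd.DataFrame:
        # Subjects whose clustering lost a network entirely have no defined
        # MSD for it; those subjects are dropped pairwise for that network.
        rows = []
        groups = cohort["group"].to_numpy()

        def contrast(y):
            ok = np.isfinite(y)
            if ok.sum() < design.X.shape[1] + 2:
                return np.nan, np.nan, np.nan
            if ok.all():
                t, p = glm_contrast(y, design)
                return t, p, cohens_d(y, groups)
            sub = build_design(cohort.loc[ok].reset_index(drop=True))
            t, p = glm_contrast(y[ok], sub)
            return t, p, cohens_d(y[ok], groups[ok])

        for desc in _DESCRIPTORS:
            df = values[desc]
            nets = [c for c in df.columns if c != "cortex"]
            pvals, entries = [], []
            for c in nets:
                t, p, d = contrast(df[c].to_numpy(dtype=float))
                entries.append({"descriptor": desc, "network": c, "t": t, "p": p,
                                "cohens_d": d})
                pvals.append(p if np.isfinite(p) else 1.0)
            padj = fdr_bh(pvals)
            for e, pa in zip(entries, padj):
                e["p_fdr"] = float(pa)
            t, p, d = contrast(df["cortex"].to_numpy(dtype=float))
            entries.append({"descriptor": desc, "network": "cortex", "t": t, "p": p,
                            "cohens_d": d, "p_fdr": float(p)})
            rows += entries
        return pd.DataFrame(rows)

    # -- fit -----------------------------------------------------------

    def fit(self, seed: int = 0, n_perm: int | None = None,
            parcelwise: bool = True, centrality: bool = True,
            spin: bool = False, n_steps: int = 100) -> IdiosyncrasyResults:
        """Run the full analysis.

        ``n_perm`` (default from the config) controls the TFCE permutation
        passes; set it to 0 to skip the parcel-wise and centrality
        contrasts. ``spin`` adds spin-test spatial correlations between the
        resulting maps.
        """
        cfg = self.config
        n_perm = cfg.n_perm if n_perm is None else n_perm
        cohort = qc_filter(self.cohort, cfg.fd_max)
        ids = cohort["id"].tolist()
        n_net = cfg.n_networks
        geo = self.geodesic
        t0 = time.time()

        fcs = {i: compute_fc(self.timeseries[i], cfg.retain_fraction) for i in ids}
        mean_fc = group_average([fcs[i] for i in ids])
        ref_emb = build_reference(mean_fc, cfg.embedding)
        ref_params, ref_assign = fit_reference_gmm(ref_emb, self.template_labels)
        ref_sizes = np.maximum(network_size(ref_assign, n_net), 1)
        logger.info("reference built in %.1fs", time.time() - t0)

        assigns, sd_rows, dd_rows, resids = {}, [], [], []
        values = {d: [] for d in _DESCRIPTORS}
        for i in ids:
            emb = diffusion_map(affinity(fcs[i], kernel=cfg.embedding.kernel),
                                cfg.embedding)
            op, aligned = change_of_basis(emb, ref_emb)
            assign = cluster_individual(aligned, ref_params, source=i)
            assigns[i] = assign
            sd = surface_distance(assign, ref_assign, geo)
            dd = diffusion_distance(aligned, ref_emb, assign, ref_assign)
            sd_rows.append(sd)
            dd_rows.append(dd)
            resids.append(op.residual)
            summ = network_summaries(assign, ref_assign, geo, n_net, sd=sd, dd=dd)
            for d in _DESCRIPTORS:
                values[d].append(summ[d])

        P = geo.n_parcels
        sd_maps = pd.DataFrame(np.vstack(sd_rows), index=ids)
        dd_maps = pd.DataFrame(np.vstack(dd_rows), index=ids)
        net_cols = [f"net{k}" for k in range(1, n_net + 1)]
        for d in _DESCRIPTORS:
            arr = np.vstack(values[d])
            df = pd.DataFrame(arr, index=ids, columns=net_cols)
            # cortex-wide: reference-size-weighted mean over defined networks
            cortex = []
            for row in arr:
                ok = np.isfinite(row)
                cortex.append(cortexwide_summary(row[ok], ref_sizes[ok]))
            df["cortex"] = cortex
            values[d] = df

        design = build_design(cohort)
        network_table = self._network_level_stats(values, design, cohort)

        groups = cohort["group"].to_numpy()
        post_typ = [assigns[i].posteriors for i, g in zip(ids, groups) if g == "typical"]
        post_atyp = [assigns[i].posteriors for i, g in zip(ids, groups) if g == "atypical"]
        entropy_table = entropy_contrast(post_typ, post_atyp,
                                         ref_assign.hard_labels, n_net)

        severity_table = None
        if cohort.loc[cohort["group"] == "atypical", "severity"].notna().sum() >= 4:
            sev_values = values["mean_dd"].copy()
            sev_values.columns = [f"dd_{c}" for c in sev_values.columns]
            sev_sd = values["mean_sd"].copy()
            sev_sd.columns = [f"sd_{c}" for c in sev_sd.columns]
            severity_table = severity_correlation(
                pd.concat([sev_values, sev_sd], axis=1), cohort)

        age_rows = []
        for desc in ("mean_sd", "mean_dd"):
            for c in values[desc].columns:
                eff = age_effect(values[desc][c].to_numpy(dtype=float), cohort)
                age_rows.append({"descriptor": desc, "network": c,
                                 "age_t": eff.age_t, "age_p": eff.age_p,
                                 "interaction_t": eff.interaction_t,
                                 "interaction_p": eff.interaction_p})
        age_table = pd.DataFrame(age_rows)
        for desc in ("mean_sd", "mean_dd"):
            m = (age_table["descriptor"] == desc) & (age_table["network"] != "cortex")
            age_table.loc[m, "age_p_fdr"] = fdr_bh(age_table.loc[m, "age_p"].to_numpy())

        adjacency = (geo.weights > 0).astype(np.int8)
        sd_statmap = dd_statmap = None
        dc_con = ec_con = None
        if parcelwise and n_perm > 0:
            sd_statmap = permutation_correct(sd_maps.to_numpy(), design, adjacency,
                                             n_perm=n_perm, seed=seed, n_steps=n_steps)
            dd_statmap = permutation_correct(dd_maps.to_numpy(), design, adjacency,
                                             n_perm=n_perm, seed=seed + 1,
                                             n_steps=n_steps)
        if centrality and n_perm > 0:
            dc = np.vstack([degree_centrality(fcs[i].correlations, cfg.centrality)
                            for i in ids]).astype(float)
            dc_con = centrality_contrast(dc, design, adjacency, with_idiosyncrasy=True,
                                         sd_maps=sd_maps.to_numpy(),
                                         dd_maps=dd_maps.to_numpy(),
                                         n_perm=n_perm, seed=seed + 2, n_steps=n_steps)
            ec = np.vstack([eigenvector_centrality(np.clip(fcs[i].correlations, 0, None))
                            for i in ids])
            ec_con = centrality_contrast(ec, design, adjacency, with_idiosyncrasy=True,
                                         sd_maps=sd_maps.to_numpy(),
                                         dd_maps=dd_maps.to_numpy(),
                                         n_perm=n_perm, seed=seed + 3, n_steps=n_steps)

        spin_tables: dict = {}
        if spin and sd_statmap is not None:
            cent = geo.centroids
            pairs = {"sd_vs_dd": (sd_statmap.t, dd_statmap.t)}
            if dc_con is not None:
                pairs["dc_vs_sd"] = (dc_con.before.t, sd_statmap.t)
                pairs["dc_vs_dd"] = (dc_con.before.t, dd_statmap.t)
            h_typ = np.asarray(post_typ).mean(axis=0)
            h_atyp = np.asarray(post_atyp).mean(axis=0)
            from .idiosyncrasy import network_entropy
            d_entropy = network_entropy([h_atyp]) - network_entropy([h_typ])
            pairs["entropy_vs_sd"] = (d_entropy, sd_statmap.t)
            pairs["entropy_vs_dd"] = (d_entropy, dd_statmap.t)
            for name, (a, b) in pairs.items():
                sn = spin_test(a, b, cent, n_rot=cfg.n_rot, seed=seed + 7)
                spin_tables[name] = sn

        grad_sd = gradient_stratification(sd_maps.to_numpy().mean(axis=0), ref_emb)
        grad_dd = gradient_stratification(dd_maps.to_numpy().mean(axis=0), ref_emb)
        logger.info("fit complete in %.1fs", time.time() - t0)

        return IdiosyncrasyResults(
            cohort=cohort, reference_embedding=ref_emb,
            reference_assignment=ref_assign, reference_gmm=ref_params,
            subject_assignments=assigns, sd_maps=sd_maps, dd_maps=dd_maps,
            network_values=values, network_table=network_table,
            entropy_table=entropy_table, severity_table=severity_table,
            age_table=age_table, sd_statmap=sd_statmap, dd_statmap=dd_statmap,
            dc_contrast=dc_con, ec_contrast=ec_con, spin_tables=spin_tables,
            gradient_sd=grad_sd, gradient_dd=grad_dd,
            config_hash=cfg.config_hash, seed=seed, n_perm=n_perm,
            alignment_residuals=pd.Series(resids, index=ids),
        )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: "iio.RunConfig", out_dir, seed: int = 0,
                 n_perm: int | None = None, resume: bool = False) -> IdiosyncrasyResults:
    """Simulate a cohort under ``config.scenario``, fit the model and write
    every artifact plus a JSON run summary to ``out_dir``.

    With ``resume=True`` an existing simulated dataset in ``out_dir`` is
    reloaded instead of regenerated, so only downstream stages rerun.
    Reruns with identical config and seed reproduce all numeric outputs.
    """
    from .synthetic import simulate_dataset, scenario_geometry

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages = {}

    ts_path = out / "timeseries.h5"
    cohort_path = out / "cohort.csv"
    if resume and ts_path.exists() and cohort_path.exists():
        logger.info("resuming: reloading simulated dataset from %s", out)
        series = iio.read_timeseries_h5(ts_path)
        cohort = iio.read_cohort(cohort_path)
        _, parc, geo, template = scenario_geometry(config.scenario)
        mesh = None
    else:
        ds = simulate_dataset(config.scenario, seed)
        series, cohort = ds.timeseries, ds.cohort
        mesh, parc, geo, template = ds.mesh, ds.parcellation, ds.geodesic, ds.template_labels
        iio.write_mesh_ply(mesh, out / "mesh.ply")
        iio.write_parcellation(parc, out / "parcellation.csv")
        iio.write_labels(template, out / "template_labels.csv")
        iio.write_cohort(cohort, cohort_path)
        iio.write_timeseries_h5(series, ts_path)
    stages["simulate"] = time.time() - t0

    model = IdiosyncrasyModel(series, cohort, geo, template, config=config)
    res = model.fit(seed=seed, n_perm=n_perm)
    stages["fit"] = time.time() - t0 - stages["simulate"]

    iio.write_embedding_h5(res.reference_embedding, out / "reference_embedding.h5")
    iio.write_labels(res.reference_assignment.hard_labels, out / "reference_networks.csv")
    res.sd_maps.rename_axis("id").to_csv(out / "sd_maps.csv", float_format="%.17g")
    res.dd_maps.rename_axis("id").to_csv(out / "dd_maps.csv", float_format="%.17g")
    res.network_table.to_csv(out / "network_stats.csv", index=False, float_format="%.17g")
    res.entropy_table.to_csv(out / "entropy_stats.csv", index=False, float_format="%.17g")
    res.age_table.to_csv(out / "age_stats.csv", index=False, float_format="%.17g")
    if res.severity_table is not None:
        res.severity_table.to_csv(out / "severity_stats.csv", index=False,
                                  float_format="%.17g")
    (out / "summary.txt").write_text(res.summary() + "\n")

    summary = {
        "config_hash": res.config_hash,
        "seed": seed,
        "n_perm": res.n_perm,
        "parameters": config.to_dict(),
        "n_subjects": len(res.cohort),
        "stage_seconds": {k: round(v, 2) for k, v in stages.items()},
        "significant_parcels": {
            "sd": None if res.sd_statmap is None else res.sd_statmap.n_significant,
            "dd": None if res.dd_statmap is None else res.dd_statmap.n_significant,
            "dc_before": None if res.dc_contrast is None else res.dc_contrast.n_significant_before,
            "dc_after": None if res.dc_contrast is None else res.dc_contrast.n_significant_after,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return res
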