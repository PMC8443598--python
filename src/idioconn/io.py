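"""Readers and writers for pipeline artifacts, and the run configuration.

Formats: ASCII PLY for meshes, CSV for tables (cohort, labels, results),
HDF5 for numeric arrays (time series, connectivity, embeddings,
posteriors), JSON for run summaries. Round trips are bit-exact for integer
fields and exact to float64 representation for floats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh
import yaml

from .centrality import CentralityConfig
from .embedding import Embedding, EmbeddingConfig
from .synthetic import (CohortConfig, Parcellation, Scenario, ShiftConfig,
                        SurfaceMesh, TimeSeriesConfig, TimeSeriesMatrix)

__all__ = [
    "write_mesh_ply", "read_mesh_ply", "write_parcellation", "read_parcellation",
    "write_labels", "read_labels", "write_cohort", "read_cohort",
    "write_timeseries_h5", "read_timeseries_h5", "write_embedding_h5",
    "read_embedding_h5", "RunConfig",
]


def write_mesh_ply(mesh: SurfaceMesh, path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_bytes(tm.export(file_type="ply", encoding="ascii"))


def read_mesh_ply(path, sphere_radius: float | None = None) -> SurfaceMesh:
    tm = trimesh.load(str(path), file_type="ply", process=False)
    verts = np.asarray(tm.vertices, dtype=float)
    radius = sphere_radius if sphere_radius is not None else float(
        np.median(np.linalg.norm(verts, axis=1)))
    return SurfaceMesh(vertices=verts, faces=np.asarray(tm.faces, dtype=int),
                       sphere_radius=radius)


def write_parcellation(parc: Parcellation, path) -> None:
    """Vertex membership plus per-parcel centroid columns in one CSV."""
    df = pd.DataFrame({"vertex_id": np.arange(len(parc.vertex_to_parcel)),
                       "parcel_id": parc.vertex_to_parcel})
    cent = pd.DataFrame(parc.parcel_centroids, columns=["cx", "cy", "cz"])
    cent.insert(0, "parcel_id", np.arange(1, parc.n_parcels + 1))
    cent["central_vertex"] = parc.central_vertices
    df.to_csv(path, index=False)
    Path(str(path)).with_suffix(".centroids.csv").write_text(
        cent.to_csv(index=False, float_format="%.17g"))


def read_parcellation(path) -> Parcellation:
    df = pd.read_csv(path)
    cent = pd.read_csv(Path(str(path)).with_suffix(".centroids.csv"))
    return Parcellation(
        vertex_to_parcel=df["parcel_id"].to_numpy(dtype=int),
        parcel_centroids=cent[["cx", "cy", "cz"]].to_numpy(dtype=float),
        central_vertices=cent["central_vertex"].to_numpy(dtype=int),
        n_parcels=len(cent),
    )


def write_labels(labels: np.ndarray, path) -> None:
    pd.DataFrame({"parcel_id": np.arange(1, len(labels) + 1),
                  "network_id": np.asarray(labels, dtype=int)}).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    return pd.read_csv(path).sort_values("parcel_id")["network_id"].to_numpy(dtype=int)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "group", "site", "age", "sex", "fd"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort file lacks column(s): {sorted(missing)}")
    return df


def write_timeseries_h5(series: dict, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("timeseries")
        for sid, ts in series.items():
            d = g.create_dataset(sid, data=ts.values)
            d.attrs["tr"] = ts.tr


def read_timeseries_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for sid, d in f["timeseries"].items():
            out[sid] = TimeSeriesMatrix(values=d[()], tr=float(d.attrs["tr"]))
    return out


def write_embedding_h5(emb: Embedding, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coordinates", data=emb.coordinates)
        f.create_dataset("eigenvalues", data=emb.eigenvalues)
        f.attrs["is_reference"] = emb.is_reference
        f.attrs["is_aligned"] = emb.is_aligned
        if emb.config is not None:
            f.attrs["alpha"] = emb.config.alpha
            f.attrs["diffusion_time"] = emb.config.diffusion_time
            f.attrs["n_components"] = emb.config.n_components
            f.attrs["kernel"] = emb.config.kernel


def read_embedding_h5(path) -> Embedding:
    with h5py.File(path, "r") as f:
        cfg = None
        if "alpha" in f.attrs:
            cfg = EmbeddingConfig(alpha=float(f.attrs["alpha"]),
                                  diffusion_time=float(f.attrs["diffusion_time"]),
                                  n_components=int(f.attrs["n_components"]),
                                  kernel=str(f.attrs["kernel"]))
        return Embedding(coordinates=f["coordinates"][()],
                         eigenvalues=f["eigenvalues"][()],
                         is_reference=bool(f.attrs["is_reference"]),
                         is_aligned=bool(f.attrs["is_aligned"]), config=cfg)


# ---------------------------------------------------------------------------
# run configuration


def _asdict(obj):
    return dataclasses.asdict(obj)


@dataclasses.dataclass
class RunConfig:
    """All pipeline settings; defaults equal the published parameters.

    retain_fraction 0.10, alpha 0.5, diffusion time 1, 30 components,
    7 networks, DC threshold 0.2, FD cutoff 0.3 mm, 1000 spin rotations;
    permutation count is configurable (the published analysis used 10,000;
    smaller counts keep desk-scale runs tractable).
    """

    scenario: Scenario = dataclasses.field(default_factory=Scenario)
    retain_fraction: float = 0.10
    embedding: EmbeddingConfig = dataclasses.field(default_factory=EmbeddingConfig)
    n_networks: int = 7
    centrality: CentralityConfig = dataclasses.field(default_factory=CentralityConfig)
    fd_max: float = 0.3
    n_perm: int = 1000
    n_rot: int = 1000
    alpha_level: float = 0.05

    def to_dict(self) -> dict:
        return {
            "scenario": _asdict(self.scenario),
            "retain_fraction": self.retain_fraction,
            "embedding": _asdict(self.embedding),
            "n_networks": self.n_networks,
            "centrality": _asdict(self.centrality),
            "fd_max": self.fd_max,
            "n_perm": self.n_perm,
            "n_rot": self.n_rot,
            "alpha_level": self.alpha_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = d.pop("scenario", {})
        scenario = Scenario(
            **{k: v for k, v in sc.items()
               if k not in ("cohort", "shift", "timeseries")},
        )
        if "cohort" in sc:
            c = dict(sc["cohort"])
            for key in ("site_names", "site_weights"):
                if key in c:
                    c[key] = tuple(c[key])
            scenario.cohort = CohortConfig(**c)
        if "shift" in sc:
            s = dict(sc["shift"])
            if "increase_networks" in s:
                s["increase_networks"] = tuple(s["increase_networks"])
            scenario.shift = ShiftConfig(**s)
        if "timeseries" in sc:
            t = dict(sc["timeseries"])
            if "site_amplitude" in t:
                t["site_amplitude"] = tuple(t["site_amplitude"])
            scenario.timeseries = TimeSeriesConfig(**t)
        emb = EmbeddingConfig(**d.pop("embedding", {}))
        cen = CentralityConfig(**d.pop("centrality", {}))
        return cls(scenario=scenario, embedding=emb, centrality=cen, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    @property
    def config_hash(self) -> str:
        """Digest of the configuration, stable under key reordering."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
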