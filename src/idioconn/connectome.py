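"""Subject- and group-level functional connectivity matrices.

Connectivity is the pairwise Pearson correlation of parcel time series,
Fisher z-transformed (correlations clipped away from +-1 to keep z finite)
and row-sparsified so that each row retains only its top 10% most similar
entries. QC filtering removes high-motion subjects before any averaging.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ConnectivityMatrix", "compute_fc", "group_average", "qc_filter"]

_R_CLIP = 1.0 - 1e-7


@dataclasses.dataclass
class ConnectivityMatrix:
    """Fisher-z functional connectivity of one subject (or a group mean).

    ``z_values`` holds the row-sparsified matrix (zeros outside the
    retained set; may be asymmetric because retention is row-wise);
    ``z_raw`` the dense pre-retention matrix, and ``correlations`` the raw
    Pearson matrix used by centrality measures.
    """

    z_values: np.ndarray
    retained_mask: np.ndarray
    sparsified: bool
    retain_fraction: float
    z_raw: np.ndarray | None = None
    correlations: np.ndarray | None = None

    @property
    def n_parcels(self) -> int:
        return self.z_values.shape[0]


def _row_sparsify(z: np.ndarray, retain_fraction: float, rank_by: str = "signed"):
    """Keep the k = round(f * (P-1)) largest off-diagonal entries per row.

    Ranking is by signed z (most positive first) by default — the natural
    reading of "most similar" — or by |z| with ``rank_by="absolute"``.
    Ties break toward the lower column index for reproducibility.
    Returns (sparse z, mask).
    """
    if rank_by not in ("signed", "absolute"):
        raise ValueError(f"unknown rank_by: {rank_by}")
    P = z.shape[0]
    k = int(round(retain_fraction * (P - 1)))
    scored = np.abs(z) if rank_by == "absolute" else z.copy()
    np.fill_diagonal(scored, -np.inf)
    order = np.argsort(-scored, axis=1, kind="stable")
    mask = np.zeros_like(z, dtype=bool)
    rows = np.repeat(np.arange(P), k)
    mask[rows, order[:, :k].ravel()] = True
    out = np.where(mask, z, 0.0)
    return out, mask


def compute_fc(ts, retain_fraction: float = 0.10,
               rank_by: str = "signed") -> ConnectivityMatrix:
    """Pearson -> clipped Fisher z -> per-row top-k retention.

    Parameters
    ----------
    ts : TimeSeriesMatrix
        Parcel time series (parcels x timepoints), positive variance.
    retain_fraction : float in (0, 1]
        Fraction of off-diagonal entries kept per row (default 10%).
    rank_by : {"signed", "absolute"}
        Whether retention ranks by signed z or by magnitude.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must lie in (0, 1]")
    x = np.asarray(ts.values, dtype=float)
    var = x.var(axis=1)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(f"zero-variance parcel(s): {bad.tolist()}")
    r = np.corrcoef(x)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    np.fill_diagonal(z, 0.0)
    z_sparse, mask = _row_sparsify(z, retain_fraction, rank_by)
    return ConnectivityMatrix(z_values=z_sparse, retained_mask=mask, sparsified=True,
                              retain_fraction=retain_fraction, z_raw=z, correlations=r)


def group_average(matrices: Sequence[ConnectivityMatrix],
                  retain_fraction: float | None = None) -> ConnectivityMatrix:
    """Element-wise mean of the *unsparsified* z matrices, sparsified once.

    Averaging already-sparsified matrices would dilute the retained-set
    semantics, so the mean is taken over the dense z matrices and the
    row-wise retention applied a single time to the result.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to average")
    shape = matrices[0].z_values.shape
    for m in matrices:
        if m.z_values.shape != shape:
            raise ValueError("connectivity matrices differ in shape")
        if m.z_raw is None:
            raise ValueError("group averaging needs the unsparsified z matrices")
    frac = retain_fraction if retain_fraction is not None else matrices[0].retain_fraction
    z_mean = np.add.reduce([m.z_raw for m in matrices]) / len(matrices)
    r_mean = np.add.reduce([m.correlations for m in matrices]) / len(matrices)
    z_sparse, mask = _row_sparsify(z_mean, frac)
    return ConnectivityMatrix(z_values=z_sparse, retained_mask=mask, sparsified=True,
                              retain_fraction=frac, z_raw=z_mean, correlations=r_mean)


def qc_filter(cohort: pd.DataFrame, fd_max: float = 0.3) -> pd.DataFrame:
    """Exclude subjects with mean framewise displacement above ``fd_max``.

    The rule is a strict inequality: fd == fd_max is retained. Excluded ids
    are logged; an empty result triggers a warning.
    """
    if "fd" not in cohort.columns:
        raise ValueError("cohort table lacks the 'fd' column")
    keep = cohort["fd"] <= fd_max
    excluded = cohort.loc[~keep, "id"].tolist()
    if excluded:
        logger.info("QC excluded %d subject(s): %s", len(excluded), excluded)
    out = cohort.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("QC filter removed every subject", stacklevel=2)
    return out
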