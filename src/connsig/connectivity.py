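"""First-level ROI-to-ROI functional connectivity.

Connectivity between two regions is the Pearson correlation of their BOLD
time series, variance-stabilized by the Fisher z-transform ``z = atanh(r)``.
Correlations are clipped away from +/-1 before the transform so that
degenerate (perfectly correlated) inputs stay finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConnMatrix", "compute_connectivity", "vectorize_lower", "CLIP_EPS"]

CLIP_EPS = 1e-7  # guard against atanh(+/-1) on degenerate series


@dataclass
class ConnMatrix:
    """Symmetric R x R matrix of Fisher-z connectivity values.

    The diagonal is undefined (self-connectivity) and stored as 0.
    """

    region_labels: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        r = len(self.region_labels)
        if self.z.shape != (r, r):
            raise ValueError("matrix shape does not match region labels")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


def compute_connectivity(ts: np.ndarray, region_labels: list[str]) -> ConnMatrix:
    """Pearson-correlate all region pairs of a T x R time-series matrix.

    Parameters
    ----------
    ts
        T x R array, T >= 3 timepoints, one column per region.
    region_labels
        Column names, length R.

    Returns
    -------
    ConnMatrix with ``z[i, j] = atanh(clip(r_ij))`` and zeroed diagonal.

    Raises
    ------
    ValueError
        If T < 3 or any column is constant (named in the message).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] != len(region_labels):
        raise ValueError("time series must be T x R matching region_labels")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = [region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for region(s): {bad}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnMatrix(region_labels=list(region_labels), z=z)


def vectorize_lower(m: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Row-major lower-triangle (i > j) edge vector of a symmetric matrix.

    The order is (1,0), (2,0), (2,1), (3,0), ... and has length R(R-1)/2.
    A useful consequence of this ordering: the edges among the first k rows/
    columns are exactly the first k(k-1)/2 entries, so nested leading
    submatrices correspond to prefixes of the vector.

    Raises
    ------
    ValueError
        If the input is asymmetric beyond ``atol``.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(m, m.T, atol=atol, rtol=0.0):
        raise ValueError("matrix is not symmetric within tolerance")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def conn_to_frame(conn: ConnMatrix) -> pd.DataFrame:
    """Represent a connectivity matrix as a labelled DataFrame."""
    return pd.DataFrame(conn.z, index=conn.region_labels, columns=conn.region_labels)


def save_conn(conn: ConnMatrix, tsv_path, sidecar_path=None) -> None:
    """Write a connectivity matrix as TSV; sidecar JSON records the masked diagonal."""
    conn_to_frame(conn).to_csv(tsv_path, sep="\t")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"diagonal": "masked (stored as 0)", "transform": "fisher-z"}, fh)


def load_conn(tsv_path) -> ConnMatrix:
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    return ConnMatrix(region_labels=list(df.columns), z=df.to_numpy())
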