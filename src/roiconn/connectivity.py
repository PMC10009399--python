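"""ROI-to-ROI Pearson connectivity, Fisher r-to-z, and network block means.

Each subject's frames x ROIs table becomes an R x R correlation matrix, each
cell is Fisher-transformed (z = atanh r), and the z matrix is reduced to six
scalars: the mean z over the within-network pair set of each of CON, DMN and
OST, and over each of the three between-network cross-pair sets.  Averaging
each ROI's intra-network z values first and then across ROIs gives exactly
the same number (both equal the ordered-pair mean), so the pair-set mean is
the single implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import PairIndex
from .signals import RoiTimeSeriesTable

#: Canonical metric column order used in every cohort table and report.
METRIC_NAMES = (
    "within_CON",
    "within_DMN",
    "within_OST",
    "between_OST_CON",
    "between_OST_DMN",
    "between_CON_DMN",
)

CLAMP_R = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson matrix (diagonal 1) and its Fisher-z transform
    (diagonal NaN — self-correlations are undefined in z units)."""

    r_values: np.ndarray
    z_values: np.ndarray
    labels: tuple[str, ...]


@dataclass(frozen=True)
class NetworkMetrics:
    """The six within/between-network Fisher-z block means for one subject."""

    subject_id: str
    within_CON: float
    within_DMN: float
    within_OST: float
    between_OST_CON: float
    between_OST_DMN: float
    between_CON_DMN: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def correlation_matrix(ts: RoiTimeSeriesTable) -> np.ndarray:
    """Pearson correlation of every ROI-column pair; diagonal exactly 1.

    Raises if any column has zero variance (naming the ROI) or if fewer than
    3 frames are available.
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 frames to correlate")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.labels[i] for i in dead]
        raise ValueError(
            f"zero-variance ROI column(s) {names} for subject {ts.subject_id!r}"
        )
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return r


def fisher_z(r: np.ndarray | float, clamp: bool = False) -> np.ndarray | float:
    """Fisher's r-to-z: z = atanh(r) = 0.5 ln((1+r)/(1-r)).

    |r| >= 1 raises by default; with ``clamp=True`` such cells are mapped to
    atanh(+-(1 - 1e-7)) instead (useful for degenerate but expected inputs,
    e.g. duplicated columns in toy data).
    """
    arr = np.asarray(r, dtype=float)
    bad = np.abs(arr) >= 1.0
    if np.any(bad):
        if not clamp:
            raise ValueError(
                "correlation magnitude >= 1 cannot be Fisher-transformed "
                "(pass clamp=True to map to +-atanh(1 - 1e-7))"
            )
        arr = np.where(bad, np.sign(arr) * CLAMP_R, arr)
    z = np.arctanh(arr)
    return float(z) if np.isscalar(r) else z


def connectivity(ts: RoiTimeSeriesTable, clamp: bool = False) -> ConnectivityMatrix:
    """Pearson matrix plus its Fisher-z transform (diagonal set to NaN)."""
    r = correlation_matrix(ts)
    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.full_like(r, np.nan)
    z[off] = np.asarray(fisher_z(r[off], clamp=clamp))
    return ConnectivityMatrix(r_values=r, z_values=z, labels=tuple(ts.labels))


def network_metrics(
    z_matrix: np.ndarray, pairs: PairIndex, subject_id: str = ""
) -> NetworkMetrics:
    """Reduce a Fisher-z matrix to the six block means.

    within_X = mean z over the unordered pair set of network X; between_XY =
    mean z over all cross pairs.  The diagonal is never touched.  Raises if
    any required cell is non-finite.
    """

    def block_mean(pair_set, name):
        idx = np.asarray(pair_set)
        vals = z_matrix[idx[:, 0], idx[:, 1]]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite z value in block {name}")
        return float(vals.mean())

    vals = {}
    for net, pair_set in pairs.within.items():
        vals[f"within_{net}"] = block_mean(pair_set, f"within_{net}")
    for (nx, ny), pair_set in pairs.between.items():
        vals[f"between_{nx}_{ny}"] = block_mean(pair_set, f"between_{nx}_{ny}")
    return NetworkMetrics(subject_id=subject_id, **vals)


def subject_metrics(
    ts: RoiTimeSeriesTable, pairs: PairIndex, clamp: bool = False
) -> NetworkMetrics:
    """Time series -> correlation -> Fisher z -> six block means."""
    cm = connectivity(ts, clamp=clamp)
    return network_metrics(cm.z_values, pairs, subject_id=ts.subject_id)


def save_matrix(cm: ConnectivityMatrix, path: str | Path, kind: str = "z") -> None:
    """Export the r or z matrix as TSV with ROI labels on both axes."""
    mat = cm.z_values if kind == "z" else cm.r_values
    df = pd.DataFrame(mat, index=list(cm.labels), columns=list(cm.labels))
    df.to_csv(path, sep="\t", float_format="%.17g")


def metrics_frame(metrics: list[NetworkMetrics]) -> pd.DataFrame:
    """Stack per-subject metrics into a subject x metric DataFrame."""
    rows = [{"subject_id": m.subject_id, **m.as_dict()} for m in metrics]
    return pd.DataFrame(rows, columns=["subject_id", *METRIC_NAMES])
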