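"""Volume I/O, ROI time-course extraction and framewise-displacement summaries.

Inputs are preprocessed 4-D BOLD volumes (NIfTI-1) or plain per-subject ROI
time-series tables; all upstream preprocessing (realignment, normalisation,
nuisance regression, filtering) is assumed done elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import Atlas, GridSpec, sphere_mask

HEAD_RADIUS_MM = 50.0


@dataclass
class Bold4D:
    """A 4-D BOLD run: data indexed (x, y, z, t), its grid, and the TR in s."""

    data: np.ndarray
    grid: GridSpec
    tr: float = 2.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"spatial shape {data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if data.shape[3] < 3:
            raise ValueError("need at least 3 frames")
        self.data = data


@dataclass
class RoiTimeSeriesTable:
    """T x R matrix of per-ROI mean signals for one subject (atlas column order)."""

    subject_id: str
    values: np.ndarray
    labels: list[str]
    tr: float = 2.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("time-series table must be 2-D (frames x ROIs)")
        if values.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"subject {self.subject_id}: non-finite time-series value")
        self.values = values

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def load_bold(path: str | Path, tr: float | None = None) -> Bold4D:
    """Read a 4-D NIfTI-1 volume. TR falls back to the header pixdim if not given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got {data.ndim}-D")
    grid = GridSpec(shape=data.shape[:3], affine=np.asarray(img.affine))
    if tr is None:
        tr = float(img.header.get_zooms()[3]) or 2.0
    return Bold4D(data=data, grid=grid, tr=tr)


def save_bold(bold: Bold4D, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.grid.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], bold.tr))
    nib.save(img, str(path))


def extract_timeseries(bold: Bold4D, atlas: Atlas, subject_id: str = "") -> RoiTimeSeriesTable:
    """Average the voxel time courses within each ROI's 5-mm sphere.

    Column j at frame t is the arithmetic mean over ROI j's sphere voxels of
    the volume at frame t.  Overlapping spheres are allowed; shared voxels
    contribute to every ROI covering them.
    """
    T = bold.data.shape[3]
    out = np.empty((T, len(atlas)))
    for j, roi in enumerate(atlas.rois):
        vox = sphere_mask(roi, bold.grid)
        block = bold.data[vox[:, 0], vox[:, 1], vox[:, 2], :]  # (n_vox, T)
        if not np.all(np.isfinite(block)):
            raise ValueError(f"non-finite voxel value inside ROI {roi.label!r}")
        out[:, j] = block.mean(axis=0)
    return RoiTimeSeriesTable(
        subject_id=subject_id, values=out, labels=atlas.labels, tr=bold.tr
    )


def framewise_displacement(
    motion: np.ndarray, head_radius: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style FD from a T x 6 motion table (3 translations mm, 3 rotations rad).

    FD(1) = 0; FD(t) = sum |d translation_i| + head_radius * sum |d rotation_i|
    over backward differences between consecutive frames.  Rotations are
    converted to arc length on a sphere of ``head_radius`` mm (default 50).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameter")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.concatenate([[0.0], d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)])
    return fd


def mean_fd(fd: np.ndarray) -> float:
    """Arithmetic mean of an FD series, including the leading zero frame."""
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    return float(fd.mean())


def load_motion_params(path: str | Path) -> np.ndarray:
    """Read a 6-column whitespace/TSV motion-parameter file (one row per frame)."""
    motion = np.loadtxt(str(path))
    if motion.ndim == 1:
        motion = motion[None, :]
    if motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {motion.shape[1]}")
    return motion


def save_motion_params(motion: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(motion, dtype=float), fmt="%.10g")


def save_timeseries(ts: RoiTimeSeriesTable, path: str | Path) -> None:
    """Write the frames x ROIs table as TSV with ROI-label header."""
    df = pd.DataFrame(ts.values, columns=ts.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_timeseries(
    path: str | Path, subject_id: str = "", tr: float = 2.0
) -> RoiTimeSeriesTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return RoiTimeSeriesTable(
        subject_id=subject_id or Path(path).stem,
        values=df.to_numpy(dtype=float),
        labels=list(df.columns),
        tr=tr,
    )
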