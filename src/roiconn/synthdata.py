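"""Seedable synthetic cohorts with block-structured ROI correlations.

The generator emulates a three-group (OCD / anxiety-control / healthy-control)
female pediatric resting-state study: per subject it draws a zero-mean
multivariate-normal ROI time series whose correlation matrix has constant
blocks, so that the six Fisher-z block means recover configurable per-group
targets; demographics (age, motion, severity scores, a depressive-disorder
flag) are drawn alongside.  All randomness flows from a single master seed
through ``numpy.random.SeedSequence`` spawning — no global state.

Default conditions: group sizes 23/26/44, T = 200 frames at TR = 2 s, ages
uniform on 8–21 years, log-normal mean framewise displacement, and
between-subject heterogeneity of 0.10 z-units around the group block
targets.  The group targets for the two metrics with real group differences
(within-CON 0.54/0.43/0.46 and OST–CON 0.40/0.30/0.33 for OCD/AC/HC) follow
the study this package models; the remaining four are group-equal plausible
resting-state values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import NETWORKS, Atlas, GridSpec, bundled_atlas, sphere_mask
from .connectivity import METRIC_NAMES, subject_metrics
from .signals import RoiTimeSeriesTable, framewise_displacement, mean_fd, \
    save_motion_params, save_timeseries
from . import signals as _signals
from .atlas import block_index

GROUP_ORDER = ("OCD", "AC", "HC")

DEFAULT_BLOCK_TARGETS: dict[str, dict[str, float]] = {
    "OCD": {"within_CON": 0.54, "within_DMN": 0.45, "within_OST": 0.35,
            "between_OST_CON": 0.40, "between_OST_DMN": 0.25, "between_CON_DMN": 0.30},
    "AC":  {"within_CON": 0.43, "within_DMN": 0.45, "within_OST": 0.35,
            "between_OST_CON": 0.30, "between_OST_DMN": 0.25, "between_CON_DMN": 0.30},
    "HC":  {"within_CON": 0.46, "within_DMN": 0.45, "within_OST": 0.35,
            "between_OST_CON": 0.33, "between_OST_DMN": 0.25, "between_CON_DMN": 0.30},
}

PSD_EIG_FLOOR = 1e-6


def _default_roi_counts() -> dict[str, int]:
    atlas = bundled_atlas()
    return {net: len(atlas.networks[net]) for net in NETWORKS}


@dataclass
class SimulationConfig:
    """Everything needed to regenerate a cohort bit-for-bit.

    ``block_targets`` maps group -> metric-name -> Fisher-z target.
    Between-subject heterogeneity has two parts: ``subject_z_sd_global`` is
    the SD (z-units) of a per-subject shift applied to all six blocks at
    once (overall connectivity level), and ``subject_z_sd`` the SD of
    independent per-block deviations.  The global part dominates by default
    because a shared shift preserves the feasibility (positive
    semidefiniteness) of the block structure, whereas large independent
    per-block deviations would routinely require repair.  ``fd_model`` is
    the (meanlog, sdlog) of the log-normal mean-FD distribution in mm.
    """

    group_sizes: tuple[int, int, int] = (23, 26, 44)
    n_frames: int = 200
    tr: float = 2.0
    roi_counts: dict[str, int] = field(default_factory=_default_roi_counts)
    block_targets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_BLOCK_TARGETS.items()})
    subject_z_sd: float = 0.05
    subject_z_sd_global: float = 0.08
    age_range: tuple[float, float] = (8.0, 21.0)
    fd_model: tuple[float, float] = (float(np.log(0.15)), 0.4)
    cybocs_model: tuple[float, float] = (23.03, 6.41)
    masc_model: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "OCD": (52.0, 15.0), "AC": (50.0, 15.0), "HC": (38.0, 15.0)})
    ocir_model: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "OCD": (21.0, 8.0), "AC": (12.0, 8.0), "HC": (6.0, 8.0)})
    masc_missing_rate: float = 11.0 / 93.0
    depress_rate: dict[str, float] = field(default_factory=lambda: {
        "OCD": 0.09, "AC": 0.15, "HC": 0.0})
    ar1: float = 0.0
    seed: int = 0
    psd_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValueError("need 3 group sizes, each >= 2")
        if self.n_frames < 10:
            raise ValueError("need at least 10 frames")
        for g, targets in self.block_targets.items():
            for name, z in targets.items():
                if not abs(np.tanh(z)) < 1.0:
                    raise ValueError(f"block target {name}={z} for {g} is not finite in r")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    age: float
    motion: np.ndarray
    timeseries: RoiTimeSeriesTable
    cybocs: float | None
    masc: float | None
    ocir: float | None
    depress_flag: int
    #: max |correlation shift| applied by PSD repair for this subject (0 = none)
    repair_deviation: float = 0.0

    @property
    def mean_fd(self) -> float:
        return mean_fd(framewise_displacement(self.motion))


@dataclass
class SimulatedCohort:
    subjects: list[SimulatedSubject]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.subjects)

    def demographics(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id, "group": s.group, "age": s.age,
                "mean_fd": s.mean_fd, "cybocs": s.cybocs, "masc": s.masc,
                "ocir": s.ocir, "depress_flag": s.depress_flag,
                "repair_deviation": s.repair_deviation,
            })
        return pd.DataFrame(rows)


def build_block_correlation(
    targets: dict[str, float],
    roi_counts: dict[str, int],
) -> tuple[np.ndarray, float]:
    """R x R correlation matrix with constant within/between-network blocks.

    Off-diagonal cells inside network X are tanh(z_within_X); cells between
    networks X and Y are tanh(z_between_XY); the diagonal is 1.  If the
    result is not positive semidefinite it is repaired by clipping
    eigenvalues at a small floor and renormalising to unit diagonal.
    Returns (matrix, max elementwise deviation from the requested values).
    """
    net_of = [net for net in NETWORKS for _ in range(roi_counts[net])]
    R = len(net_of)
    raw = np.eye(R)
    for i in range(R):
        for j in range(i + 1, R):
            ni, nj = net_of[i], net_of[j]
            if ni == nj:
                z = targets[f"within_{ni}"]
            else:
                key = f"between_{ni}_{nj}"
                alt = f"between_{nj}_{ni}"
                z = targets[key] if key in targets else targets[alt]
            raw[i, j] = raw[j, i] = np.tanh(z)
    w, V = np.linalg.eigh(raw)
    if w.min() >= PSD_EIG_FLOOR:
        return raw, 0.0
    w = np.clip(w, PSD_EIG_FLOOR, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    off = ~np.eye(R, dtype=bool)
    deviation = float(np.abs(fixed - raw)[off].max())
    return fixed, deviation


def simulate_subject(
    corr: np.ndarray,
    n_frames: int,
    seed: int | np.random.SeedSequence,
    labels: list[str] | None = None,
    subject_id: str = "",
    tr: float = 2.0,
    ar1: float = 0.0,
) -> RoiTimeSeriesTable:
    """Draw T frames from a zero-mean MVN with the given correlation matrix.

    Mixing uses the symmetric matrix square root (eigendecomposition);
    ``ar1`` optionally gives each latent innovation series an AR(1)
    autocorrelation with unit marginal variance.  Deterministic per seed.
    """
    corr = np.asarray(corr, dtype=float)
    R = corr.shape[0]
    w, V = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    root = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, R))
    if ar1:
        phi = float(ar1)
        innov = z * np.sqrt(1.0 - phi ** 2)
        innov[0] = z[0]
        for t in range(1, n_frames):
            innov[t] += phi * innov[t - 1]
        z = innov
    values = z @ root.T
    if labels is None:
        labels = [f"roi{i}" for i in range(R)]
    return RoiTimeSeriesTable(subject_id=subject_id, values=values, labels=labels, tr=tr)


def _simulate_motion(n_frames: int, target_mean_fd: float, rng: np.random.Generator) -> np.ndarray:
    """T x 6 motion table whose Power FD series has exactly the target mean.

    Per-frame displacements are exponential draws rescaled so that the mean
    of the FD series (with its leading zero) equals ``target_mean_fd``; each
    frame's displacement is realised as a sign-alternating x-translation.
    """
    steps = rng.exponential(1.0, size=n_frames - 1)
    steps *= target_mean_fd * n_frames / steps.sum()
    signs = np.where(np.arange(n_frames - 1) % 2 == 0, 1.0, -1.0)
    motion = np.zeros((n_frames, 6))
    motion[1:, 0] = np.cumsum(signs * steps)
    return motion


def simulate_cohort(config: SimulationConfig, atlas: Atlas | None = None) -> SimulatedCohort:
    """Generate the full synthetic cohort described by ``config``.

    Per-group block targets are realised up to zero-mean between-subject
    heterogeneity (global + per-block); ages are uniform on ``age_range``;
    mean FD is
    log-normal; CYBOCS exists only for the OCD group.  Per-subject seeds are
    spawned deterministically from the master seed.
    """
    if atlas is not None:
        labels = atlas.labels
        roi_counts = {net: len(atlas.networks[net]) for net in NETWORKS}
        if roi_counts != dict(config.roi_counts):
            raise ValueError(
                f"atlas network sizes {roi_counts} disagree with config {config.roi_counts}")
    else:
        labels = None
        roi_counts = dict(config.roi_counts)

    master = np.random.SeedSequence(config.seed)
    n_total = sum(config.group_sizes)
    seqs = master.spawn(n_total + 1)
    demo_rng = np.random.default_rng(seqs[0])

    subjects: list[SimulatedSubject] = []
    k = 0
    for group, n in zip(GROUP_ORDER, config.group_sizes):
        targets = config.block_targets[group]
        for i in range(n):
            sid = f"{group}{i + 1:02d}"
            subj_seq = seqs[1 + k]
            subj_rng = np.random.default_rng(subj_seq)
            shift = demo_rng.normal(0.0, config.subject_z_sd_global)
            jitter = demo_rng.normal(0.0, config.subject_z_sd, size=len(METRIC_NAMES))
            subj_targets = {
                name: targets[name] + shift + jitter[m]
                for m, name in enumerate(METRIC_NAMES)
            }
            corr, dev = build_block_correlation(subj_targets, roi_counts)
            if dev > config.psd_tolerance:
                raise ValueError(
                    f"PSD repair moved correlations by {dev:.4f} > "
                    f"psd_tolerance={config.psd_tolerance} for subject {sid}")
            ts = simulate_subject(
                corr, config.n_frames, subj_seq.spawn(1)[0],
                labels=labels, subject_id=sid, tr=config.tr, ar1=config.ar1)
            age = float(demo_rng.uniform(*config.age_range))
            fd_target = float(np.exp(demo_rng.normal(*config.fd_model)))
            motion = _simulate_motion(config.n_frames, fd_target, subj_rng)
            cybocs = None
            if group == "OCD":
                mu, sd = config.cybocs_model
                cybocs = float(np.clip(round(demo_rng.normal(mu, sd)), 0, 40))
            masc = None
            if demo_rng.uniform() >= config.masc_missing_rate:
                mu, sd = config.masc_model[group]
                masc = float(max(0.0, round(demo_rng.normal(mu, sd))))
            mu, sd = config.ocir_model[group]
            ocir = float(max(0.0, round(demo_rng.normal(mu, sd))))
            depress = int(demo_rng.uniform() < config.depress_rate[group])
            subjects.append(SimulatedSubject(
                subject_id=sid, group=group, age=age, motion=motion,
                timeseries=ts, cybocs=cybocs, masc=masc, ocir=ocir,
                depress_flag=depress, repair_deviation=dev))
            k += 1
    return SimulatedCohort(subjects=subjects, config=config)


def cohort_table(cohort: SimulatedCohort, atlas: Atlas | None = None) -> pd.DataFrame:
    """Demographics plus the six connectivity metrics computed per subject."""
    if atlas is None:
        atlas = bundled_atlas()
    pairs = block_index(atlas)
    demo = cohort.demographics()
    metric_rows = []
    for s in cohort.subjects:
        m = subject_metrics(s.timeseries, pairs)
        metric_rows.append(m.as_dict())
    metrics = pd.DataFrame(metric_rows)
    return pd.concat([demo.reset_index(drop=True), metrics], axis=1)


def grid_covering(atlas: Atlas, voxel_mm: float = 4.0, pad_mm: float = 8.0) -> GridSpec:
    """Smallest axis-aligned isotropic grid containing every sphere plus padding."""
    centers = np.array([r.center_mni for r in atlas.rois])
    radii = np.array([r.radius_mm for r in atlas.rois])
    lo = (centers - radii[:, None]).min(axis=0) - pad_mm
    hi = (centers + radii[:, None]).max(axis=0) + pad_mm
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / voxel_mm)) + 1 for d in range(3))
    return GridSpec.isotropic(shape, voxel_mm, lo)


def write_cohort_nifti(
    cohort: SimulatedCohort,
    atlas: Atlas,
    grid: GridSpec,
    out_dir: str | Path,
    background_sd: float = 1.0,
) -> Path:
    """Embed each subject's ROI series into a 4-D volume on ``grid``.

    Every voxel of ROI j's sphere carries ROI j's series (overlap voxels get
    the mean of the contributing ROIs); all other voxels get seeded Gaussian
    noise with SD ``background_sd``.  Writes one .nii.gz plus a motion text
    file per subject, the cohort demographics CSV, and a manifest recording
    the config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    masks = [sphere_mask(roi, grid) for roi in atlas.rois]
    bg_seqs = np.random.SeedSequence(
        (cohort.config.seed, 0xB6)).spawn(len(cohort.subjects))
    for s, bg_seq in zip(cohort.subjects, bg_seqs):
        T = s.timeseries.n_frames
        rng = np.random.default_rng(bg_seq)
        data = rng.normal(0.0, background_sd, size=(*grid.shape, T))
        hit = np.zeros(grid.shape, dtype=int)
        for m in masks:
            np.add.at(hit, (m[:, 0], m[:, 1], m[:, 2]), 1)
        stacked = np.zeros((*grid.shape, T))
        for j, m in enumerate(masks):
            stacked[m[:, 0], m[:, 1], m[:, 2], :] += s.timeseries.values[:, j]
        covered = hit > 0
        data[covered] = stacked[covered] / hit[covered, None]
        bold = _signals.Bold4D(data=data, grid=grid, tr=s.timeseries.tr)
        _signals.save_bold(bold, out / f"{s.subject_id}_bold.nii.gz")
        save_motion_params(s.motion, out / f"{s.subject_id}_motion.txt")
    cohort.demographics().to_csv(out / "cohort.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cohort.config.to_dict()}, fh, indent=2, default=float)
    return out


def write_cohort_tables(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Per-subject time-series TSVs + motion files + demographics + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        save_timeseries(s.timeseries, out / f"{s.subject_id}_timeseries.tsv")
        save_motion_params(s.motion, out / f"{s.subject_id}_motion.txt")
    cohort.demographics().to_csv(out / "cohort.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cohort.config.to_dict()}, fh, indent=2, default=float)
    return out
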