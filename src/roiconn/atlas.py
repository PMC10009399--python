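"""Seed-sphere ROI atlases over the CON, DMN and OST networks.

An atlas is an ordered list of spherical seeds, each a labelled MNI-space
center with a radius (default 5 mm).  The ROI order is fixed and defines the
row/column order of every downstream connectivity matrix.  Three networks are
recognised:

* ``CON`` — cingulo-opercular network (posterior medial frontal cortex,
  frontal operculum, anterior insula),
* ``DMN`` — default mode network (precuneus, posterior cingulate, medial
  prefrontal, angular gyrus, medial temporal nodes),
* ``OST`` — orbitofrontal–striatal–thalamic circuit.

The shipped file ``data/atlas_ost_con_dmn_synthetic.tsv`` is a synthetic
reconstruction of such a seed table, with literature-style MNI coordinates;
it is a stand-in, not a transcription of any published coordinate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NETWORKS = ("CON", "DMN", "OST")
#: The three unordered network pairs, in reporting order.
NETWORK_PAIRS = (("OST", "CON"), ("OST", "DMN"), ("CON", "DMN"))

DEFAULT_RADIUS_MM = 5.0


@dataclass(frozen=True)
class RoiSpec:
    """One labelled spherical seed.

    Parameters
    ----------
    label : str
        Unique short name, e.g. ``"dACC"``.
    network : str
        One of ``"CON"``, ``"DMN"``, ``"OST"``.
    center_mni : ndarray, shape (3,)
        Sphere center in MNI152 world coordinates (mm).
    radius_mm : float
        Sphere radius in mm, default 5.
    """

    label: str
    network: str
    center_mni: np.ndarray
    radius_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise ValueError(
                f"unknown network {self.network!r} for ROI {self.label!r}; "
                f"expected one of {NETWORKS}"
            )
        center = np.asarray(self.center_mni, dtype=float)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise ValueError(f"ROI {self.label!r}: center must be a finite 3-vector")
        object.__setattr__(self, "center_mni", center)
        if not self.radius_mm > 0:
            raise ValueError(f"ROI {self.label!r}: radius must be positive")


@dataclass(frozen=True)
class GridSpec:
    """A 3-D sampling grid: voxel shape plus a voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("grid shape must be 3 positive integers")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(
        cls, shape: tuple[int, int, int], voxel_mm: float, origin_mni: Iterable[float]
    ) -> "GridSpec":
        """Axis-aligned grid with cubic voxels; voxel (0,0,0) sits at ``origin_mni``."""
        affine = np.eye(4)
        affine[:3, :3] *= voxel_mm
        affine[:3, 3] = np.asarray(list(origin_mni), dtype=float)
        return cls(shape, affine)


@dataclass(frozen=True)
class Atlas:
    """Ordered ROI set; `networks` maps each network name to ROI indices."""

    rois: tuple[RoiSpec, ...]
    networks: Mapping[str, tuple[int, ...]] = field(init=False)

    def __post_init__(self) -> None:
        rois = tuple(self.rois)
        if not rois:
            raise ValueError("no ROIs")
        labels = [r.label for r in rois]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate ROI label(s): {sorted(dupes)}")
        networks = {
            net: tuple(i for i, r in enumerate(rois) if r.network == net)
            for net in NETWORKS
        }
        thin = [net for net, idx in networks.items() if len(idx) < 2]
        if thin:
            raise ValueError(
                f"network(s) {thin} have fewer than 2 ROIs; "
                "within-network means need at least one pair"
            )
        object.__setattr__(self, "rois", rois)
        object.__setattr__(self, "networks", networks)

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]


@dataclass(frozen=True)
class PairIndex:
    """Within/between-network ROI-pair index sets for the six block metrics.

    ``within[net]`` holds unordered index pairs (i < j) inside ``net``;
    ``between[(X, Y)]`` holds all cross pairs (i in X, j in Y).
    """

    within: Mapping[str, tuple[tuple[int, int], ...]]
    between: Mapping[tuple[str, str], tuple[tuple[int, int], ...]]


def load_atlas(path: str | Path) -> Atlas:
    """Read a seed table (TSV with columns label, network, x, y, z, [radius]).

    Row order is preserved; a missing radius column (or blank cell) gets the
    5 mm default.  Raises on duplicate labels, unknown network tokens,
    non-numeric coordinates, an empty file, or any network with < 2 ROIs.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"label", "network", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atlas file missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError("no ROIs in atlas file")
    rois = []
    for _, row in df.iterrows():
        try:
            center = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric coordinate for ROI {row['label']!r}"
            ) from exc
        radius = DEFAULT_RADIUS_MM
        if "radius" in df.columns and pd.notna(row["radius"]):
            radius = float(row["radius"])
        rois.append(
            RoiSpec(
                label=str(row["label"]),
                network=str(row["network"]),
                center_mni=center,
                radius_mm=radius,
            )
        )
    return Atlas(tuple(rois))


def bundled_atlas() -> Atlas:
    """The synthetic CON/DMN/OST seed atlas shipped with the package."""
    with resources.as_file(
        resources.files("roiconn.data") / "atlas_ost_con_dmn_synthetic.tsv"
    ) as p:
        return load_atlas(p)


def sphere_mask(roi: RoiSpec, grid: GridSpec) -> np.ndarray:
    """Voxel indices of the ROI's sphere on ``grid``.

    A voxel belongs to the sphere iff the Euclidean distance from its center's
    world coordinate to ``roi.center_mni`` is <= ``roi.radius_mm``.  Returns an
    (n, 3) integer array sorted lexicographically; raises if the sphere
    contains no voxel center of the grid.
    """
    inv = np.linalg.inv(grid.affine)
    center_vox = inv[:3, :3] @ roi.center_mni + inv[:3, 3]
    # Bounding box in voxel space: radius divided by the smallest singular
    # value bounds how far (in voxel units) a within-radius point can be.
    smin = np.linalg.svd(grid.affine[:3, :3], compute_uv=False).min()
    reach = int(np.ceil(roi.radius_mm / smin)) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - reach, 0)
    hi = np.minimum(np.ceil(center_vox).astype(int) + reach, np.array(grid.shape) - 1)
    if np.any(lo > hi):
        raise ValueError(f"sphere for ROI {roi.label!r} lies entirely outside the grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[d], hi[d] + 1) for d in range(3)), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = vox @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    dist = np.linalg.norm(world - roi.center_mni, axis=1)
    keep = vox[dist <= roi.radius_mm]
    if keep.size == 0:
        raise ValueError(
            f"sphere for ROI {roi.label!r} contains no voxel center of the grid"
        )
    order = np.lexsort((keep[:, 2], keep[:, 1], keep[:, 0]))
    return keep[order]


def union_mask_volume(atlas: Atlas, grid: GridSpec) -> np.ndarray:
    """Integer label volume (0 = background, ROI index + 1 elsewhere).

    Overlapping spheres: the later ROI wins in the label volume; this export
    is for visual inspection only and does not feed extraction.
    """
    vol = np.zeros(grid.shape, dtype=np.int16)
    for i, roi in enumerate(atlas.rois):
        m = sphere_mask(roi, grid)
        vol[m[:, 0], m[:, 1], m[:, 2]] = i + 1
    return vol


def block_index(atlas: Atlas) -> PairIndex:
    """Enumerate the six metric blocks: 3 within-network and 3 between-network.

    Within pairs exclude self-pairs; between pairs cover every (ROI in X,
    ROI in Y) exactly once.  With k ROIs in a network there are k(k-1)/2
    within pairs; with kX and kY there are kX*kY between pairs.
    """
    within = {}
    for net in NETWORKS:
        idx = atlas.networks[net]
        within[net] = tuple(
            (idx[a], idx[b]) for a in range(len(idx)) for b in range(a + 1, len(idx))
        )
    between = {}
    for netx, nety in NETWORK_PAIRS:
        between[(netx, nety)] = tuple(
            (i, j) for i in atlas.networks[netx] for j in atlas.networks[nety]
        )
    return PairIndex(within=within, between=between)
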