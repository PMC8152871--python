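"""Sphere-ROI time-series extraction from 4D volumes.

Each region's signal is the unweighted mean over the voxels whose
centers fall within a fixed radius (6 mm by default) of the region's
MNI peak coordinate; membership is inclusive (``<= radius``) and is
decided in mm space through the image affine.  Extracted per-run series
are z-scored per region within each run to discount global run-to-run
signal differences, then a participant's runs are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelSet",
    "RoiTimeSeriesSet",
    "RoiError",
    "sphere_mask",
    "extract_roi_series",
    "extract_from_nifti",
    "normalize_run",
    "concatenate_runs",
]


class RoiError(ValueError):
    """Raised for extraction contract violations (empty masks, flat series...)."""


@dataclass(frozen=True)
class VoxelSet:
    """Voxel indices of one spherical ROI on a given image grid.

    ``indices`` is an (n, 3) integer array of 0-based voxel index
    triples; ``affine`` maps voxel indices to MNI mm.
    """

    affine: np.ndarray
    indices: np.ndarray
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """Grid step along each voxel axis (mm)."""
        return tuple(float(np.linalg.norm(self.affine[:3, k])) for k in range(3))

    def centers_mm(self) -> np.ndarray:
        """World-space (mm) centers of the member voxels, shape (n, 3)."""
        homog = np.c_[self.indices, np.ones(len(self.indices))]
        return (homog @ self.affine.T)[:, :3]


@dataclass(frozen=True)
class RoiTimeSeriesSet:
    """Region x time signal matrix for one participant (one run or pooled runs).

    ``data`` has shape (n_regions, n_timepoints); ``tr_s`` is the
    sampling interval in seconds; ``run_boundaries`` records the
    cumulative timepoint offsets of the pooled runs (for audit and for
    run-respecting randomization).
    """

    participant: str
    run: str
    data: np.ndarray
    tr_s: float
    region_names: tuple[str, ...]
    run_boundaries: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise RoiError("time-series data must be a 2-D region x time matrix")
        if data.shape[0] != len(self.region_names):
            raise RoiError(
                f"{data.shape[0]} rows but {len(self.region_names)} region names"
            )
        if not np.all(np.isfinite(data)):
            raise RoiError("time-series data contains non-finite values")
        object.__setattr__(self, "data", data)
        if not self.run_boundaries:
            object.__setattr__(self, "run_boundaries", (data.shape[1],))

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def run_slices(self) -> list[slice]:
        """Slices delimiting the pooled runs along the time axis."""
        edges = (0,) + self.run_boundaries
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def sphere_mask(
    center_mm: Sequence[float],
    radius_mm: float,
    affine: np.ndarray,
    shape: Sequence[int],
) -> VoxelSet:
    """Voxels whose centers lie within ``radius_mm`` of ``center_mm`` (inclusive).

    ``affine`` is the 4x4 voxel-to-mm map of the image grid with
    ``shape`` (first three axes).  Raises :class:`RoiError` when the
    sphere captures no voxel of the grid.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise RoiError("affine must be 4x4")
    if radius_mm < 0:
        raise RoiError("radius must be non-negative")
    center_mm = np.asarray(center_mm, dtype=float)
    inv = np.linalg.inv(affine)  # raises LinAlgError if singular
    center_vox = (inv @ np.append(center_mm, 1.0))[:3]

    # candidate bounding box in voxel space, clipped to the grid
    steps = np.array([np.linalg.norm(affine[:3, k]) for k in range(3)])
    lo = np.maximum(np.floor(center_vox - radius_mm / steps - 1), 0).astype(int)
    hi = np.minimum(np.ceil(center_vox + radius_mm / steps + 1), np.array(shape[:3]) - 1).astype(int)
    if np.any(lo > hi):
        raise RoiError(
            f"sphere at {tuple(center_mm)} mm (r={radius_mm}) lies outside the grid"
        )
    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = np.c_[grid, np.ones(len(grid))] @ affine.T
    dist = np.linalg.norm(centers[:, :3] - center_mm, axis=1)
    members = grid[dist <= radius_mm + 1e-9]
    if len(members) == 0:
        raise RoiError(
            f"sphere at {tuple(center_mm)} mm (r={radius_mm}) contains no voxel center"
        )
    return VoxelSet(
        affine=affine,
        indices=members,
        center_mm=tuple(float(v) for v in center_mm),
        radius_mm=float(radius_mm),
    )


def extract_roi_series(
    volumes,
    masks: Sequence[VoxelSet],
    region_names: Sequence[str] | None = None,
    participant: str = "",
    run: str = "",
    tr_s: float = 2.0,
) -> RoiTimeSeriesSet:
    """Average the 4D image over each mask to get region x time series.

    ``volumes`` is a nibabel spatial image or a 4-D ndarray
    (x, y, z, t).  Entry (region, t) is the unweighted mean of the
    mask's voxel values at volume t.
    """
    if hasattr(volumes, "get_fdata"):
        data = np.asarray(volumes.get_fdata())
        tr_img = getattr(volumes.header, "get_zooms", lambda: ())()
        if len(tr_img) >= 4 and tr_img[3] > 0:
            tr_s = float(tr_img[3])
    else:
        data = np.asarray(volumes, dtype=float)
    if data.ndim != 4:
        raise RoiError("volumes must be 4-D (x, y, z, t)")
    if region_names is None:
        region_names = [f"region_{k}" for k in range(len(masks))]
    if len(region_names) != len(masks):
        raise RoiError("one region name per mask required")

    n_t = data.shape[3]
    out = np.empty((len(masks), n_t))
    for k, mask in enumerate(masks):
        idx = mask.indices
        if np.any(idx < 0) or np.any(idx >= np.array(data.shape[:3])):
            raise RoiError(f"mask for region {region_names[k]!r} exceeds the image grid")
        vox = data[idx[:, 0], idx[:, 1], idx[:, 2], :]  # (n_vox, t)
        finite = np.isfinite(vox)
        if not np.all(finite.any(axis=0)):
            t_bad = int(np.flatnonzero(~finite.any(axis=0))[0])
            raise RoiError(
                f"region {region_names[k]!r}: no finite voxel value at volume {t_bad}"
            )
        out[k] = np.nanmean(np.where(finite, vox, np.nan), axis=0)
    return RoiTimeSeriesSet(
        participant=participant,
        run=run,
        data=out,
        tr_s=tr_s,
        region_names=tuple(region_names),
    )


def extract_from_nifti(
    path,
    catalog,
    radius_mm: float = 6.0,
    participant: str = "",
    run: str = "",
) -> RoiTimeSeriesSet:
    """Sphere-extract every catalog region from a 4D NIfTI file.

    Builds one ``radius_mm`` sphere per region from the image affine
    and averages; the TR is taken from the NIfTI header when present.
    """
    img = nib.load(str(path))
    affine = img.affine
    shape = img.shape
    if len(shape) != 4:
        raise RoiError(f"{path}: expected a 4-D image, got shape {shape}")
    masks = [
        sphere_mask(region.center_mm, radius_mm, affine, shape[:3])
        for region in catalog
    ]
    return extract_roi_series(
        img,
        masks,
        region_names=[r.name for r in catalog],
        participant=participant,
        run=run,
    )


def normalize_run(
    ts: RoiTimeSeriesSet, *, detrend: bool = False, center_only: bool = False
) -> RoiTimeSeriesSet:
    """Z-score each region's series within each run (mean 0, sd 1).

    ``detrend`` removes a linear trend per region per run first;
    ``center_only`` subtracts the run mean without rescaling.  A
    zero-variance (flat) series is a hard error: it signals a degenerate
    extraction rather than data to be silently passed through.
    """
    data = ts.data.copy()
    for sl in ts.run_slices():
        block = data[:, sl]
        if detrend and block.shape[1] > 1:
            t = np.arange(block.shape[1], dtype=float)
            t -= t.mean()
            slope = (block @ t) / (t @ t)
            block = block - slope[:, None] * t
        mean = block.mean(axis=1, keepdims=True)
        block = block - mean
        if not center_only:
            sd = block.std(axis=1, ddof=1, keepdims=True)
            flat = np.flatnonzero(sd.ravel() == 0)
            if flat.size:
                raise RoiError(
                    f"region {ts.region_names[flat[0]]!r} has zero variance in "
                    f"run window [{sl.start}, {sl.stop}) — flat extraction"
                )
            block = block / sd
        data[:, sl] = block
    return replace(ts, data=data, run_boundaries=ts.run_boundaries)


def concatenate_runs(runs: Sequence[RoiTimeSeriesSet]) -> RoiTimeSeriesSet:
    """Pool a participant's runs along time, recording run boundaries."""
    if not runs:
        raise RoiError("no runs to concatenate")
    first = runs[0]
    for r in runs[1:]:
        if r.region_names != first.region_names:
            raise RoiError(
                f"region-order mismatch between runs {first.run!r} and {r.run!r}"
            )
        if r.tr_s != first.tr_s:
            raise RoiError("sampling-interval mismatch across runs")
    if len(runs) == 1:
        return first
    data = np.concatenate([r.data for r in runs], axis=1)
    boundaries = tuple(np.cumsum([r.n_timepoints for r in runs]).tolist())
    return RoiTimeSeriesSet(
        participant=first.participant,
        run="+".join(r.run for r in runs),
        data=data,
        tr_s=first.tr_s,
        region_names=first.region_names,
        run_boundaries=boundaries,
    )
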