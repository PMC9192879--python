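"""Condylar region-of-interest volumetry and HU densitometry.

The condylar ROI is the slab of segmented bone from the condylar apex to
a point 15 mm further down the condylar axis.  Membership is decided on
voxel centres with a half-open interval ``[0, depth)`` along the axis, so
the 15 mm boundary plane never double-counts.  Volume is the foreground
voxel count times the per-voxel volume (a segmentation-software readout,
not a mesh integral); density is the arithmetic mean HU over the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import BinaryMask, CtVolume

__all__ = [
    "CondyleRoi",
    "DensityRecord",
    "clip_condylar_roi",
    "mask_volume",
    "mean_density",
    "density_change",
    "DEFAULT_ROI_DEPTH_MM",
]

DEFAULT_ROI_DEPTH_MM = 15.0


@dataclass(frozen=True)
class CondyleRoi:
    """Provenance of a clipped condylar ROI."""

    mask: BinaryMask
    axis: np.ndarray  # unit vector pointing down the condylar axis
    apex: np.ndarray  # mm
    depth: float  # mm


@dataclass(frozen=True)
class DensityRecord:
    """Mean HU and volume of one condylar ROI at one timepoint."""

    mean_hu: float
    voxel_count: int
    volume_mm3: float
    timepoint: str = ""
    side: str = ""


def _axis_projection(mask: BinaryMask, axis: np.ndarray, apex: np.ndarray) -> np.ndarray:
    """Signed distance of every voxel centre below the apex along ``axis``.

    The projection is affine in the indices, so it is assembled from three
    1-D arrays instead of a full meshgrid.
    """
    sp = np.asarray(mask.spacing)
    org = np.asarray(mask.origin)
    c0 = float(np.dot(org - apex, axis))
    parts = [
        c0 + np.arange(mask.shape[0]) * sp[0] * axis[0],
        np.arange(mask.shape[1]) * sp[1] * axis[1],
        np.arange(mask.shape[2]) * sp[2] * axis[2],
    ]
    return parts[0][:, None, None] + parts[1][None, :, None] + parts[2][None, None, :]


def clip_condylar_roi(
    mask: BinaryMask,
    axis: np.ndarray,
    apex: np.ndarray,
    depth: float | None = DEFAULT_ROI_DEPTH_MM,
) -> BinaryMask:
    """Clip ``mask`` to the slab ``[0, depth)`` mm below ``apex`` along ``axis``.

    ``axis`` must be a unit vector pointing *down* the condylar axis (away
    from the apex, toward the gonion).  ``depth=None`` (or ``inf``) keeps
    the whole mask.
    """
    if mask.count() == 0:
        raise ValueError("mask is empty")
    axis = np.asarray(axis, float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("axis must be unit-length")
    apex = np.asarray(apex, float)
    lo = mask.origin
    hi = np.asarray(mask.origin) + (np.array(mask.shape) - 1) * np.asarray(mask.spacing)
    if np.any(apex < np.asarray(lo) - 1e-9) or np.any(apex > hi + 1e-9):
        raise ValueError(f"apex {apex.tolist()} lies outside the mask bounding box")
    if depth is None or np.isinf(depth):
        return BinaryMask(mask.data.copy(), mask.spacing, mask.origin)
    if depth <= 0:
        raise ValueError("ROI empty: depth must be positive (check apex/axis)")
    t = _axis_projection(mask, axis, apex)
    clipped = mask.data & (t >= 0.0) & (t < depth)
    if not clipped.any():
        raise ValueError("ROI empty: check apex/axis")
    return BinaryMask(clipped, mask.spacing, mask.origin)


def mask_volume(mask: BinaryMask, spacing: tuple[float, float, float] | None = None) -> float:
    """Foreground voxel count times per-voxel volume, in mm^3."""
    vv = float(np.prod(spacing)) if spacing is not None else mask.voxel_volume
    return mask.count() * vv


def mean_density(volume: CtVolume, mask: BinaryMask) -> float:
    """Arithmetic mean HU over the mask foreground."""
    mask.require_congruent(volume)
    if mask.count() == 0:
        raise ValueError("cannot compute mean density of an empty mask")
    return float(volume.data[mask.data].mean())


def density_change(pre: DensityRecord, post: DensityRecord) -> float:
    """Percent change of mean HU, ``100·(post − pre)/pre``."""
    if pre.side and post.side and pre.side != post.side:
        raise ValueError("density records are from different sides")
    if pre.mean_hu == 0:
        raise ZeroDivisionError("percent change undefined: pre mean HU is zero")
    return 100.0 * (post.mean_hu - pre.mean_hu) / pre.mean_hu
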