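"""Quantitative-map summaries over liver regions and the cT1 normal limit."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import ValidationError
from .volumetric_io import VoxelVolume

__all__ = ["RegionSummary", "region_summary", "classify_ct1", "CT1_UPPER_LIMIT_MS"]

#: upper limit of normal for liver cT1 (ms); elevation is strict (> limit)
CT1_UPPER_LIMIT_MS = 795.0

_MAP_KINDS = {"ct1_ms", "pdff_percent", "t2star_ms"}


@dataclass(frozen=True)
class RegionSummary:
    median: float
    iqr_lo: float
    iqr_hi: float
    mean: float
    n_voxels: int


def _resample_to(map_vol: VoxelVolume, target: VoxelVolume) -> np.ndarray:
    """Nearest-neighbour sample of a map at the target grid's voxel centres.

    Multi-slice maps live on their own grid; matching is done in mm space
    through both affines.  Voxels outside the map grid come back NaN.
    """
    shape = target.data.shape
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    mm = target.voxel_centres_mm(idx)
    inv = np.linalg.inv(map_vol.affine)
    map_idx = (mm @ inv[:3, :3].T) + inv[:3, 3]
    out = ndimage.map_coordinates(
        map_vol.data.astype(float),
        map_idx.T,
        order=0,
        mode="constant",
        cval=np.nan,
    )
    return out.reshape(shape)


def region_summary(
    map_vol: VoxelVolume,
    region: VoxelVolume,
    lesions: list[VoxelVolume] | None = None,
) -> RegionSummary:
    """Summarise a quantitative map over ``region`` minus all lesions.

    Median and IQR use linear interpolation between order statistics.
    Raises if the region is empty after lesion exclusion (or holds no
    finite map values).
    """
    if map_vol.kind not in _MAP_KINDS:
        raise ValidationError(f"not a quantitative map: kind {map_vol.kind!r}")
    if region.kind != "mask":
        raise ValidationError("region must be a binary mask")

    sel = region.data.astype(bool)
    for lesion in lesions or ():
        if lesion.kind != "mask":
            raise ValidationError("lesion masks must be binary")
        if not lesion.same_grid(region):
            raise ValidationError("lesion mask is not on the region grid")
        sel &= ~lesion.data.astype(bool)
    if not sel.any():
        raise ValidationError("region is empty after lesion exclusion")

    if map_vol.same_grid(region):
        values = map_vol.data.astype(float)[sel]
    else:
        values = _resample_to(map_vol, region)[sel]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("no finite map values inside the region")

    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return RegionSummary(
        median=float(q50),
        iqr_lo=float(q25),
        iqr_hi=float(q75),
        mean=float(values.mean()),
        n_voxels=int(values.size),
    )


def classify_ct1(ct1_summary_ms: float, threshold_ms: float = CT1_UPPER_LIMIT_MS) -> str:
    """'elevated' iff the summary exceeds the upper limit of normal (strict)."""
    if not np.isfinite(ct1_summary_ms):
        raise ValidationError("cT1 summary must be finite")
    return "elevated" if ct1_summary_ms > threshold_ms else "normal"
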