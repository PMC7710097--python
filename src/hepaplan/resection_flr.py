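"""Virtual hepatectomy: apply a resection plan and compute the planned FLR.

A plan removes whole Couinaud segments and/or wedge resections modelled as
conical frustra from the liver surface down past the tumour.  The future
liver remnant (FLR) is reported as a parenchymal fraction: tumour voxels
are excluded from both numerator and denominator, since tumour tissue
contributes no function and planned resections always carry their tumour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._exceptions import ValidationError
from .volumetric_io import VoxelVolume

__all__ = [
    "WedgeSpec",
    "ResectionPlan",
    "FLRResult",
    "wedge_mask",
    "apply_plan",
    "resected_fraction",
]

#: inclusive lower bound on the resected fraction for model eligibility
MIN_RESECTED_FRACTION = 0.10


@dataclass(frozen=True)
class WedgeSpec:
    """An atypical wedge resection around one tumour.

    The wedge is the conical frustrum whose axis runs from ``entry_point_mm``
    on the liver surface through the tumour centroid; its small face is the
    tumour's bounding disc dilated by ``margin_mm``, and it widens toward
    the surface with half-angle ``cone_angle_deg``.  When ``entry_point_mm``
    is omitted the shortest path from the tumour centroid to the liver
    surface is used (direct surgical access).
    """

    tumour_id: str
    entry_point_mm: tuple | None = None
    margin_mm: float = 10.0
    cone_angle_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValidationError("margin_mm must be >= 0")
        if not (0 <= self.cone_angle_deg < 90):
            raise ValidationError("cone_angle_deg must be in [0, 90)")


@dataclass(frozen=True)
class ResectionPlan:
    segments_removed: frozenset = frozenset()
    wedges: tuple = ()

    def __post_init__(self) -> None:
        segs = frozenset(int(s) for s in self.segments_removed)
        if not segs <= set(range(1, 9)):
            raise ValidationError("segments_removed must be a subset of 1..8")
        object.__setattr__(self, "segments_removed", segs)
        object.__setattr__(self, "wedges", tuple(self.wedges))


@dataclass(frozen=True)
class FLRResult:
    flr_percent: float
    remnant_mask: VoxelVolume
    resected_volume_ml: float
    total_parenchyma_ml: float
    lesion_volume_ml: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.flr_percent <= 100.0):
            raise ValidationError("flr_percent outside [0, 100]")


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def wedge_mask(liver: VoxelVolume, tumour: VoxelVolume, spec: WedgeSpec) -> VoxelVolume:
    """Voxelise the conical-frustrum wedge for one tumour.

    The returned mask is intersected with the liver and always contains
    the tumour dilated by ``margin_mm``.
    """
    if liver.kind != "mask" or tumour.kind != "mask":
        raise ValidationError("wedge_mask expects binary masks")
    liv = liver.data.astype(bool)
    tum = tumour.data.astype(bool)
    if np.any(tum & ~liv):
        raise ValidationError("tumour mask is not contained in the liver mask")
    if not tum.any():
        raise ValidationError("tumour mask is empty")

    tum_pts = tumour.voxel_centres_mm()
    centroid = tum_pts.mean(axis=0)

    surf_idx = _surface_voxels(liv)
    surf_pts = liver.voxel_centres_mm(surf_idx)
    if spec.entry_point_mm is None:
        entry = surf_pts[np.argmin(np.linalg.norm(surf_pts - centroid, axis=1))]
    else:
        entry = np.asarray(spec.entry_point_mm, dtype=float)
        d_surf = np.min(np.linalg.norm(surf_pts - entry, axis=1))
        if d_surf > 5.0:
            raise ValidationError(
                f"entry point is {d_surf:.1f} mm from the liver surface (max 5 mm)"
            )

    axis = centroid - entry
    axis_len = np.linalg.norm(axis)
    if axis_len < 1e-9:
        # zero-depth limit: tumour at the surface; wedge = dilated tumour
        return liver.with_data(
            (_dilate_mm(tum, tumour.spacing, spec.margin_mm) & liv).astype(np.uint8)
        )
    u = axis / axis_len

    t_tum = (tum_pts - entry) @ u
    perp = np.linalg.norm(tum_pts - entry - np.outer(t_tum, u), axis=1)
    t_far = float(t_tum.max() + spec.margin_mm)
    r_small = float(perp.max() + spec.margin_mm)
    tan_a = math.tan(math.radians(spec.cone_angle_deg))

    liv_idx = np.argwhere(liv)
    pts = liver.voxel_centres_mm(liv_idx)
    t = (pts - entry) @ u
    r = np.linalg.norm(pts - entry - np.outer(t, u), axis=1)
    allowed = r_small + np.clip(t_far - t, 0.0, None) * tan_a
    inside = (t >= 0.0) & (t <= t_far) & (r <= allowed)

    wedge = np.zeros_like(liv)
    wedge[tuple(liv_idx[inside].T)] = True
    wedge |= _dilate_mm(tum, tumour.spacing, spec.margin_mm) & liv
    return liver.with_data(wedge.astype(np.uint8))


def _dilate_mm(mask: np.ndarray, spacing: np.ndarray, margin_mm: float) -> np.ndarray:
    if margin_mm <= 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def apply_plan(
    liver: VoxelVolume,
    labels: VoxelVolume,
    tumours: dict,
    plan: ResectionPlan,
) -> FLRResult:
    """Execute a resection plan and compute the planned FLR.

    ``tumours`` maps tumour_id -> binary VoxelVolume.  The remnant mask is
    the liver parenchyma (liver minus all tumours) not covered by any
    removed segment or wedge.
    """
    if liver.kind != "mask" or labels.kind != "labelmap":
        raise ValidationError("apply_plan expects a liver mask and a label map")
    liv = liver.data.astype(bool)
    lab = labels.data
    if np.any((lab > 0) != liv):
        raise ValidationError("label map does not partition the liver mask")

    for wedge in plan.wedges:
        if wedge.tumour_id not in tumours:
            raise ValidationError(f"plan references unknown tumour {wedge.tumour_id!r}")

    tumour_union = np.zeros_like(liv)
    for tid, tum in tumours.items():
        td = tum.data.astype(bool)
        if np.any(td & ~liv):
            raise ValidationError(f"tumour {tid!r} is not contained in the liver")
        tumour_union |= td

    resected = np.isin(lab, sorted(plan.segments_removed)) & liv
    for wedge in plan.wedges:
        resected |= wedge_mask(liver, tumours[wedge.tumour_id], wedge).data.astype(bool)

    parenchyma = liv & ~tumour_union
    remnant = parenchyma & ~resected
    vox_ml = liver.voxel_volume_mm3 / 1000.0

    n_par = int(parenchyma.sum())
    if n_par == 0:
        raise ValidationError("liver has no parenchymal voxels outside tumours")
    n_rem = int(remnant.sum())
    return FLRResult(
        flr_percent=100.0 * n_rem / n_par,
        remnant_mask=liver.with_data(remnant.astype(np.uint8), kind="mask"),
        resected_volume_ml=(n_par - n_rem) * vox_ml,
        total_parenchyma_ml=n_par * vox_ml,
        lesion_volume_ml=float(tumour_union.sum()) * vox_ml,
    )


def resected_fraction(result: FLRResult) -> float:
    """Fraction of parenchyma removed; >= 0.10 qualifies for the model set."""
    return 1.0 - result.flr_percent / 100.0


def meets_resected_threshold(
    fraction: float, threshold: float = MIN_RESECTED_FRACTION
) -> bool:
    """Inclusive eligibility test, tolerant of float rounding at the
    boundary (an FLR of exactly 90% counts as 10% resected)."""
    return fraction >= threshold - 1e-9
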