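"""Volume and table I/O.

Carries NIfTI volumes (masks, label maps, quantitative maps) with their
grid-to-scanner-mm affine, reads landmark and cohort CSVs, computes mask
volumes, and applies the field-of-view coverage rule (a liver is excluded
when more than 5% of its estimated volume lies outside the acquisition
grid).

All geometry downstream is done in scanner millimetres: grid indices are
0-based and map to mm through the affine.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from ._exceptions import DimensionalityError, SchemaError, ValidationError

__all__ = [
    "VOLUME_KINDS",
    "LANDMARK_NAMES",
    "COHORT_COLUMNS",
    "VoxelVolume",
    "LandmarkSet",
    "FovCoverage",
    "read_volume",
    "write_volume",
    "mask_volume_ml",
    "check_fov_coverage",
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
]

VOLUME_KINDS = frozenset({"mask", "labelmap", "ct1_ms", "pdff_percent", "t2star_ms"})

LANDMARK_NAMES = (
    "ivc_inferior",
    "ivc_superior",
    "rhv",
    "mhv",
    "lhv",
    "gallbladder_fossa",
    "umbilical_fissure",
    "portal_left",
    "portal_right",
)

#: required columns of the per-patient-visit cohort table (long format; one
#: row per patient and day, day -1 = pre-op, 0..5 = post-op, >=90 follow-up)
COHORT_COLUMNS = (
    "patient_id",
    "age_y",
    "sex",
    "bmi",
    "day",
    "inr",
    "bilirubin_umol_l",
    "creatinine_umol_l",
    "clavien_dindo",
    "los_days",
    "ct1_ms",
    "pdff_percent",
    "flr_percent",
    "liver_volume_ml",
    "lesion_volume_ml",
    "nas_ballooning",
    "nas_inflammation",
    "nas_steatosis",
    "ishak",
)

FOV_EXCLUSION_FRACTION = 0.05


@dataclass
class VoxelVolume:
    """A 3D scalar or label grid with a grid-index -> scanner-mm affine.

    Parameters
    ----------
    data
        3D array. Masks must be binary {0, 1}; label maps non-negative
        integers; quantitative maps any float (NaN = unmapped voxel).
    affine
        4x4 invertible matrix mapping (i, j, k, 1) voxel indices to
        scanner coordinates in millimetres.
    kind
        One of ``VOLUME_KINDS``.
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} axes"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        if self.kind not in VOLUME_KINDS:
            raise ValidationError(f"unknown volume kind {self.kind!r}")
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacing must be strictly positive")
        if self.kind == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError("mask volumes may only contain {0, 1}")
            self.data = self.data.astype(np.uint8)
        elif self.kind == "labelmap":
            if not np.issubdtype(self.data.dtype, np.integer):
                if not np.all(self.data == np.round(self.data)):
                    raise ValidationError("label maps must hold integers")
                self.data = self.data.astype(np.int32)
            if self.data.min() < 0:
                raise ValidationError("label maps must be non-negative")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centres_mm(self, index: np.ndarray | None = None) -> np.ndarray:
        """Scanner-mm coordinates of voxel centres.

        ``index`` is an (n, 3) integer array; defaults to all foreground
        voxels (non-zero entries of ``data``).
        """
        if index is None:
            index = np.argwhere(self.data != 0)
        return nib.affines.apply_affine(self.affine, np.asarray(index, dtype=float))

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "VoxelVolume":
        """A new volume on the same grid."""
        return VoxelVolume(data=data, affine=self.affine.copy(), kind=kind or self.kind)

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass(frozen=True)
class LandmarkSet:
    """The nine named anatomical points (scanner mm) used for segmentation."""

    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise SchemaError(f"landmark set missing: {', '.join(missing)}")
        clean = {}
        for name in LANDMARK_NAMES:
            p = np.asarray(self.points[name], dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {name!r} is not finite")
            clean[name] = p
        if np.allclose(clean["ivc_inferior"], clean["ivc_superior"]):
            raise ValidationError("ivc_inferior and ivc_superior coincide")
        object.__setattr__(self, "points", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply a rigid transform x -> R x + t to every landmark."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        return LandmarkSet({n: R @ p + t for n, p in self.points.items()})


@dataclass(frozen=True)
class FovCoverage:
    """Result of the field-of-view truncation check."""

    truncated_fraction: float
    excluded: bool

    @property
    def status(self) -> str:
        return "excluded" if self.excluded else "included"


def read_volume(path: os.PathLike | str, kind: str = "mask") -> VoxelVolume:
    """Load a NIfTI-1/2 volume; ``kind`` is caller metadata."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavours
        raise IOError(f"cannot read volume {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path!s}: expected a 3D volume, got {data.ndim} axes"
        )
    return VoxelVolume(data=data, affine=img.affine, kind=kind)


def write_volume(vol: VoxelVolume, path: os.PathLike | str) -> None:
    data = vol.data
    if vol.kind in ("mask", "labelmap"):
        data = data.astype(np.int16 if vol.kind == "labelmap" else np.uint8)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def mask_volume_ml(mask: VoxelVolume) -> float:
    """Foreground volume in mL (voxel count x voxel volume / 1000)."""
    if mask.kind != "mask":
        raise ValidationError(f"expected a mask volume, got kind {mask.kind!r}")
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3 / 1000.0


def _fit_ellipsoid_axes(coords: np.ndarray):
    """Moment fit of a uniform solid ellipsoid: centre, rotation, semi-axes.

    For a uniform ellipsoid the covariance eigenvalues are (semi-axis)^2/5.
    """
    centre = coords.mean(axis=0)
    cov = np.cov((coords - centre).T)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-9, None)
    return centre, evecs, np.sqrt(5.0 * evals)


def check_fov_coverage(
    mask: VoxelVolume,
    threshold: float = FOV_EXCLUSION_FRACTION,
    n_iter: int = 10,
) -> FovCoverage:
    """Estimate the liver fraction truncated at the grid boundary.

    A mask with no foreground voxel on any grid face is complete
    (fraction 0).  Otherwise the truncated part is extrapolated by an
    iterative moment fit of a solid ellipsoid: virtual voxels are placed
    where the fitted ellipsoid extends beyond the grid, the fit is
    refreshed including them, and the truncated fraction is the virtual
    share of the final fit.  Exclusion is strict: fraction must exceed
    ``threshold`` (default 5%).
    """
    if mask.kind != "mask":
        raise ValidationError("check_fov_coverage expects a binary mask")
    data = mask.data.astype(bool)
    if not data.any():
        return FovCoverage(0.0, False)
    touches = (
        data[0].any() or data[-1].any()
        or data[:, 0].any() or data[:, -1].any()
        or data[:, :, 0].any() or data[:, :, -1].any()
    )
    if not touches:
        return FovCoverage(0.0, False)

    sp = mask.spacing
    idx = np.argwhere(data)
    obs = idx * sp  # orthogonal index-space mm coords; rotation irrelevant to volume
    lo = -0.5 * sp
    hi = (np.array(data.shape) - 0.5) * sp
    n_obs = len(obs)

    virt = np.empty((0, 3))
    fraction = 0.0
    for _ in range(n_iter):
        pts = obs if len(virt) == 0 else np.vstack([obs, virt])
        centre, rot, axes = _fit_ellipsoid_axes(pts)
        # sample the fitted ellipsoid on a grid over its bounding box
        half = np.sqrt(((rot * axes[None, :]) ** 2).sum(axis=1))
        grids = [
            np.arange(
                np.floor((centre[a] - half[a]) / sp[a]) * sp[a],
                centre[a] + half[a] + sp[a],
                sp[a],
            )
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*grids, indexing="ij")
        pts_all = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        local = (pts_all - centre) @ rot
        inside = np.sum((local / axes) ** 2, axis=1) <= 1.0
        outside_grid = np.any((pts_all < lo) | (pts_all > hi), axis=1)
        virt_new = pts_all[inside & outside_grid]
        new_fraction = len(virt_new) / max(len(virt_new) + n_obs, 1)
        converged = abs(new_fraction - fraction) < 1e-4
        virt, fraction = virt_new, new_fraction
        if converged:
            break
    return FovCoverage(float(fraction), bool(fraction > threshold))


def read_landmarks(path: os.PathLike | str) -> LandmarkSet:
    """Read a landmark CSV with columns name, x_mm, y_mm, z_mm."""
    df = pd.read_csv(path)
    required = {"name", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path!s}: landmark CSV missing columns: {', '.join(sorted(missing))}"
        )
    points = {
        str(row["name"]): np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)
        for _, row in df.iterrows()
    }
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path: os.PathLike | str) -> None:
    rows = [
        {"name": n, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
        for n, p in landmarks.points.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path: os.PathLike | str) -> pd.DataFrame:
    """Read and validate the long-format cohort CSV.

    Values are in the declared units of the schema (bilirubin and
    creatinine in umol/L); conversion to scoring units happens in
    :mod:`hepaplan.scores`.
    """
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path!s}: cohort CSV missing columns: {', '.join(sorted(missing))}"
        )
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns: {', '.join(sorted(missing))}")
    return df
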