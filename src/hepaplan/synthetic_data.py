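"""Synthetic inputs: analytic liver phantoms and statistical cohorts.

``make_phantom`` builds a voxelised ellipsoid liver with landmarks placed
so that all cutting planes pass through the phantom's vertical axis, plus
closed-form per-segment volumes to serve as an oracle for the voxel
pipeline.  ``synthetic_cohort`` draws patient tables with the documented
distributional structure (logit-normal FLR, log-normal cT1/PDFF matched
to target medians/IQRs, a logistic outcome model on (ln FLR, cT1), 5-day
blood trajectories with optional early discharge, and follow-up volumes
whose regeneration is linked to the composite risk score).

Phantom geometry oracle
-----------------------
With every cutting plane containing the z axis, a segment's region is an
azimuthal sector crossed with a superior/inferior cap.  For the ellipsoid
x^2/a^2 + y^2/b^2 + z^2/c^2 <= 1 the sector fraction is independent of z
(cross-sections scale both in-plane axes equally), and equals the measure
of the sector in the elliptic parameter t, where tan t = (a/b) tan theta.
Cap volumes are the classic ellipsoid z-slab integrals.  The oracle
evaluates the documented sidedness conventions with plain 2D trigonometry
— it never calls the voxel labelling code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .scores import hepatica_score
from .volumetric_io import COHORT_COLUMNS, LandmarkSet, VoxelVolume

__all__ = [
    "Phantom",
    "make_phantom",
    "CohortEffect",
    "synthetic_cohort",
    "preop_table",
]


@dataclass(frozen=True)
class Phantom:
    liver: VoxelVolume
    landmarks: LandmarkSet
    tumours: dict
    analytic_segment_volumes_ml: dict
    analytic_total_ml: float


DEFAULT_PLANE_OFFSETS = {
    "rhv_deg": 45.0,
    "mhv_deg": 90.0,
    "lhv_deg": 160.0,
    "umbilical_deg": 135.0,
    "portal_z_mm": 0.0,
}


def _sector_fractions(offsets: dict, a: float, b: float, n_angles: int = 360_000):
    """Azimuthal measure (elliptic parameter t) of each sector group.

    Reproduces the documented sidedness conventions with 2D trigonometry:
    rhv normal points away from the mhv direction, mhv normal toward the
    rhv direction, umbilical normal toward the mhv direction; ties fall on
    the positive side.  Returns fractions for the right-posterior (6/7),
    right-anterior (5/8), medial (4) and left (2/3) sectors.
    """
    th_r = math.radians(offsets["rhv_deg"])
    th_m = math.radians(offsets["mhv_deg"])
    th_u = math.radians(offsets["umbilical_deg"])

    def oriented_normal(plane_theta: float, anchor_theta: float, toward: bool):
        n = np.array([math.sin(plane_theta), -math.cos(plane_theta)])
        anchor = np.array([math.cos(anchor_theta), math.sin(anchor_theta)])
        s = float(n @ anchor)
        if abs(s) < 1e-12:
            raise ValidationError("phantom plane anchors are degenerate")
        if (s < 0) if toward else (s > 0):
            n = -n
        return n

    n_rhv = oriented_normal(th_r, th_m, toward=False)
    n_mhv = oriented_normal(th_m, th_r, toward=True)
    n_umb = oriented_normal(th_u, th_m, toward=True)

    theta = (np.arange(n_angles) + 0.5) * (2 * math.pi / n_angles)
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    s_rhv = xy @ n_rhv
    s_mhv = xy @ n_mhv
    s_umb = xy @ n_umb
    right_post = s_rhv >= 0
    right_ant = ~right_post & (s_mhv >= 0)
    medial = ~right_post & ~right_ant & (s_umb >= 0)
    left = ~right_post & ~right_ant & ~medial

    # dt/dtheta for tan t = (a/b) tan theta
    w = (a * b) / (b**2 * np.cos(theta) ** 2 + a**2 * np.sin(theta) ** 2)
    total = w.sum()
    return {
        "right_post": float(w[right_post].sum() / total),
        "right_ant": float(w[right_ant].sum() / total),
        "medial": float(w[medial].sum() / total),
        "left": float(w[left].sum() / total),
    }


def _cap_volume_above(a: float, b: float, c: float, d: float) -> float:
    """Volume of the ellipsoid above the plane z = d (closed form)."""
    d = float(np.clip(d, -c, c))
    return math.pi * a * b * ((c - d) - (c**3 - d**3) / (3 * c**2))


def make_phantom(
    shape: str = "ellipsoid",
    radii_mm: tuple = (80.0, 70.0, 60.0),
    spacing_mm: tuple = (1.0, 1.0, 1.0),
    plane_offsets: dict | None = None,
    tumours: list | None = None,
    margin_mm: float = 8.0,
) -> Phantom:
    """Voxelise an ellipsoid (or sphere) liver with landmarks and oracle.

    ``plane_offsets`` gives the azimuth (degrees) of the rhv/mhv/lhv/
    umbilical planes around the vertical IVC axis and the portal plane
    height ``portal_z_mm``; the defaults cut the standard test phantom.
    ``tumours`` is a list of ``{"id": str, "centre_mm": (x,y,z),
    "radius_mm": r}`` dicts; each sphere must lie inside the liver.
    The analytic oracle assumes the caudate cylinder is disabled.
    """
    if shape not in ("ellipsoid", "sphere"):
        raise ValidationError(f"unknown phantom shape {shape!r}")
    radii = np.asarray(radii_mm, dtype=float)
    if shape == "sphere":
        radii = np.full(3, radii[0])
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(radii <= 2 * spacing):
        raise ValidationError("phantom radii must exceed twice the voxel spacing")
    offsets = {**DEFAULT_PLANE_OFFSETS, **(plane_offsets or {})}
    a, b, c = radii

    half = radii + margin_mm
    n_vox = np.ceil(2 * half / spacing).astype(int)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -half + spacing / 2.0  # voxel centre 0 at -half + sp/2

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in n_vox], indexing="ij")
    xs = affine[0, 0] * ii + affine[0, 3]
    ys = affine[1, 1] * jj + affine[1, 3]
    zs = affine[2, 2] * kk + affine[2, 3]
    inside = (xs / a) ** 2 + (ys / b) ** 2 + (zs / c) ** 2 <= 1.0
    liver = VoxelVolume(inside.astype(np.uint8), affine, kind="mask")

    R = 1.5 * max(a, b)
    z_top = c + 15.0
    pz = float(offsets["portal_z_mm"])

    def on_circle(deg: float, z: float = 0.0) -> np.ndarray:
        t = math.radians(deg)
        return np.array([R * math.cos(t), R * math.sin(t), z])

    th_u = offsets["umbilical_deg"]
    landmarks = LandmarkSet(
        {
            "ivc_inferior": np.array([0.0, 0.0, -z_top]),
            "ivc_superior": np.array([0.0, 0.0, z_top]),
            "rhv": on_circle(offsets["rhv_deg"]),
            "mhv": on_circle(offsets["mhv_deg"]),
            "lhv": on_circle(offsets["lhv_deg"]),
            "umbilical_fissure": on_circle(th_u, 10.0),
            "gallbladder_fossa": -on_circle(th_u, 10.0),
            "portal_left": np.array([-30.0, -5.0, pz]),
            "portal_right": np.array([30.0, 5.0, pz]),
        }
    )

    tumour_vols: dict = {}
    for spec in tumours or ():
        centre = np.asarray(spec["centre_mm"], dtype=float)
        r = float(spec["radius_mm"])
        t_inside = (xs - centre[0]) ** 2 + (ys - centre[1]) ** 2 + (
            zs - centre[2]
        ) ** 2 <= r**2
        if np.any(t_inside & ~inside):
            raise ValidationError(f"tumour {spec.get('id')!r} extends outside the liver")
        tumour_vols[str(spec.get("id", f"t{len(tumour_vols)}"))] = VoxelVolume(
            t_inside.astype(np.uint8), affine.copy(), kind="mask"
        )

    fracs = _sector_fractions(offsets, a, b)
    v_total = 4.0 / 3.0 * math.pi * a * b * c
    v_sup = _cap_volume_above(a, b, c, pz)
    v_inf = v_total - v_sup
    analytic = {
        1: 0.0,
        2: fracs["left"] * v_sup / 1000.0,
        3: fracs["left"] * v_inf / 1000.0,
        4: fracs["medial"] * v_total / 1000.0,
        5: fracs["right_ant"] * v_inf / 1000.0,
        6: fracs["right_post"] * v_inf / 1000.0,
        7: fracs["right_post"] * v_sup / 1000.0,
        8: fracs["right_ant"] * v_sup / 1000.0,
    }
    return Phantom(
        liver=liver,
        landmarks=landmarks,
        tumours=tumour_vols,
        analytic_segment_volumes_ml=analytic,
        analytic_total_ml=v_total / 1000.0,
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortEffect:
    """Logistic outcome model: logit(p) = beta0 + beta_logflr*ln(FLR%) +
    beta_ct1*cT1."""

    beta0: float = -1.2
    beta_logflr: float = -2.26
    beta_ct1: float = 0.013


def _lognormal_from_median_iqr(median: float, iqr: tuple) -> tuple:
    """(mu, sigma) of a log-normal hitting the target median and IQR width."""
    if not (0 < iqr[0] < median < iqr[1]):
        raise ValidationError(f"infeasible median/IQR: {median}, {iqr}")
    z75 = 0.6744897501960817
    mu = math.log(median)
    sigma = (math.log(iqr[1]) - math.log(iqr[0])) / (2 * z75)
    return mu, sigma


def _logitnormal_from_median_iqr(median_pct: float, iqr_pct: tuple) -> tuple:
    """(mu, sigma) of a logit-normal on (0, 100) percent."""
    vals = (iqr_pct[0], median_pct, iqr_pct[1])
    if not all(0 < v < 100 for v in vals) or not iqr_pct[0] < median_pct < iqr_pct[1]:
        raise ValidationError(f"infeasible FLR median/IQR: {median_pct}, {iqr_pct}")
    z75 = 0.6744897501960817

    def logit(p):
        return math.log(p / (1 - p))

    mu = logit(median_pct / 100.0)
    sigma = (logit(iqr_pct[1] / 100.0) - logit(iqr_pct[0] / 100.0)) / (2 * z75)
    return mu, sigma


_DAY_PROFILE = np.array([1.0, 1.18, 1.25, 1.10, 0.95])  # peak around day 2-3


def synthetic_cohort(
    n: int,
    effect: CohortEffect = CohortEffect(),
    flr_median: float = 82.8,
    flr_iqr: tuple = (61.0, 94.6),
    ct1_median: float = 722.5,
    ct1_iqr: tuple = (689.2, 772.5),
    pdff_median: float = 3.9,
    pdff_iqr: tuple = (2.5, 8.0),
    bilirubin_median: float = 10.0,
    bilirubin_iqr: tuple = (8.0, 19.0),
    age_median: float = 64.0,
    age_iqr: tuple = (56.0, 72.0),
    male_fraction: float = 97.0 / 143.0,
    blood_noise: float = 0.10,
    missing_day_prob: float = 0.15,
    regen_link: float = 6.0,
    regen_noise: float = 0.25,
    followup_fraction: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a long-format synthetic cohort (one row per patient-visit).

    Returns a table in the :data:`~hepaplan.volumetric_io.COHORT_COLUMNS`
    schema: day -1 pre-op covariates, days 1..5 post-op bloods (late days
    dropped with probability ``missing_day_prob`` to mimic early
    discharge), and a day-99 follow-up volume row.  Identical seeds give
    bit-identical tables.
    """
    if n < 10:
        raise ValidationError("synthetic cohorts need n >= 10")
    for p in (missing_day_prob, followup_fraction, male_fraction):
        if not 0.0 <= p <= 1.0:
            raise ValidationError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)

    mu_f, sd_f = _logitnormal_from_median_iqr(flr_median, flr_iqr)
    flr = 100.0 / (1.0 + np.exp(-rng.normal(mu_f, sd_f, n)))
    mu_c, sd_c = _lognormal_from_median_iqr(ct1_median, ct1_iqr)
    ct1 = np.exp(rng.normal(mu_c, sd_c, n))
    mu_p, sd_p = _lognormal_from_median_iqr(pdff_median, pdff_iqr)
    pdff = np.exp(rng.normal(mu_p, sd_p, n))
    mu_b, sd_b = _lognormal_from_median_iqr(bilirubin_median, bilirubin_iqr)
    bili0 = np.exp(rng.normal(mu_b, sd_b, n))

    z75 = 0.6744897501960817
    age = np.clip(rng.normal(age_median, (age_iqr[1] - age_iqr[0]) / (2 * z75), n), 20, 95)
    sex = np.where(rng.random(n) < male_fraction, "M", "F")
    bmi = np.clip(np.exp(rng.normal(math.log(27.0), 0.15, n)), 16, 55)
    creat0 = np.clip(rng.normal(75.0, 12.0, n), 35, None)
    inr0 = np.clip(rng.normal(1.05, 0.06, n), 0.8, None)
    liver_vol = np.clip(rng.normal(1600.0, 250.0, n), 800, None)
    lesion_vol = np.exp(rng.normal(math.log(25.0), 1.0, n))

    eta = effect.beta0 + effect.beta_logflr * np.log(flr) + effect.beta_ct1 * ct1
    p_poor = 1.0 / (1.0 + np.exp(-eta))
    outcome_true = rng.random(n) < p_poor
    # post-op blood derangement tracks the realised outcome (plus a mild
    # probability term) so the 5-day-sum upper quartile aligns with truth
    severity = 1.0 + 1.2 * outcome_true + 0.4 * p_poor

    # ordinal histology linked to the imaging biomarkers
    def ordinal(latent: np.ndarray, cuts: np.ndarray) -> np.ndarray:
        return np.digitize(latent, cuts)

    z_ct1 = (np.log(ct1) - mu_c) / sd_c + 0.8 * rng.standard_normal(n)
    z_pdff = (np.log(pdff) - mu_p) / sd_p + 0.5 * rng.standard_normal(n)
    nas_balloon = ordinal(z_ct1, np.array([0.8, 1.8]))
    nas_inflam = ordinal(z_ct1 + 0.3 * rng.standard_normal(n), np.array([0.7, 1.9]))
    nas_steat = ordinal(z_pdff, np.array([0.3, 1.2, 2.1]))
    ishak = np.clip(np.round(1.2 * z_ct1 + 1.0), 0, 6).astype(int)

    ct1_elev = ct1 > 795.0
    los = np.maximum(
        2,
        np.round(
            4.0 + 1.5 * ct1_elev + 2.0 * p_poor + rng.gamma(2.0, 0.8, n)
        ),
    ).astype(int)
    cd = np.clip(rng.binomial(3, 0.12 + 0.5 * p_poor), 0, 5)

    hep = np.array([hepatica_score(f, t) for f, t in zip(flr, ct1)])
    regen_frac = 1.0 / (
        1.0
        + np.exp(
            -(regen_link * (hep - 0.5) + regen_noise * rng.standard_normal(n))
        )
    )
    remnant = liver_vol * flr / 100.0
    followup_vol = remnant + regen_frac * (liver_vol - remnant)
    has_followup = rng.random(n) < followup_fraction

    discharge = np.where(
        rng.random(n) < missing_day_prob, rng.integers(2, 5, n), 5
    )

    rows = []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        base = {
            "patient_id": pid,
            "age_y": round(float(age[i]), 1),
            "sex": sex[i],
            "bmi": round(float(bmi[i]), 1),
            "los_days": int(los[i]),
            "ct1_ms": np.nan,
            "pdff_percent": np.nan,
            "flr_percent": np.nan,
            "liver_volume_ml": np.nan,
            "lesion_volume_ml": np.nan,
            "nas_ballooning": np.nan,
            "nas_inflammation": np.nan,
            "nas_steatosis": np.nan,
            "ishak": np.nan,
            "inr": np.nan,
            "bilirubin_umol_l": np.nan,
            "creatinine_umol_l": np.nan,
            "clavien_dindo": np.nan,
        }
        rows.append(
            {
                **base,
                "day": -1,
                "inr": round(float(inr0[i]), 2),
                "bilirubin_umol_l": round(float(bili0[i]), 1),
                "creatinine_umol_l": round(float(creat0[i]), 1),
                "clavien_dindo": 0,
                "ct1_ms": round(float(ct1[i]), 1),
                "pdff_percent": round(float(pdff[i]), 2),
                "flr_percent": round(float(flr[i]), 2),
                "liver_volume_ml": round(float(liver_vol[i]), 1),
                "lesion_volume_ml": round(float(lesion_vol[i]), 1),
                "nas_ballooning": int(nas_balloon[i]),
                "nas_inflammation": int(nas_inflam[i]),
                "nas_steatosis": int(nas_steat[i]),
                "ishak": int(ishak[i]),
                "outcome_poor_true": int(outcome_true[i]),
            }
        )
        for d in range(1, 6):
            if d > discharge[i]:
                continue
            prof = _DAY_PROFILE[d - 1]
            noise = 1.0 + blood_noise * rng.standard_normal(3)
            sev = severity[i]
            inr_d = max(0.8, inr0[i] * (1 + 0.15 * (sev - 1)) * (1 + 0.2 * (prof - 1)) * noise[0])
            bil_d = max(1.0, bili0[i] * prof * sev * noise[1])
            cre_d = max(30.0, creat0[i] * (1 + 0.35 * (sev - 1)) * (1 + 0.25 * (prof - 1)) * noise[2])
            rows.append(
                {
                    **base,
                    "day": d,
                    "inr": round(float(inr_d), 2),
                    "bilirubin_umol_l": round(float(bil_d), 1),
                    "creatinine_umol_l": round(float(cre_d), 1),
                    "clavien_dindo": int(cd[i]),
                }
            )
        if has_followup[i]:
            rows.append(
                {
                    **base,
                    "day": 99,
                    "liver_volume_ml": round(float(followup_vol[i]), 1),
                }
            )

    # schema columns first, then the generator's ground-truth extras
    # (outcome_poor_true is the latent Bernoulli outcome of the logistic
    # model, kept for validation studies; downstream code never needs it)
    df = pd.DataFrame(rows, columns=[*COHORT_COLUMNS, "outcome_poor_true"])
    return df


def preop_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """One pre-operative (day -1) row per patient."""
    pre = cohort[cohort["day"] == -1]
    if pre["patient_id"].duplicated().any():
        raise ValidationError("duplicate pre-op rows")
    return pre.reset_index(drop=True)
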