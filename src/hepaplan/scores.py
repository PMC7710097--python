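"""Per-patient derived scores and outcome labels.

Implements the daily and 5-day-summed modified Hyder-Pawlik score
(2.5*INR + 17.1*bilirubin[mg/dL] + 88.4*creatinine[mg/dL]), the day-3
Hyder-Pawlik score with Clavien-Dindo weighting, the Hepatica composite
exp(-(1.24 + ln(FLR%) * -2.26 + cT1 * 0.013)), achieved-regeneration
scoring, carry-forward imputation of incomplete post-operative blood
series, and cohort-level outcome labelling (sum > 22 or upper quartile).

Unit note: the SI->conventional conversions (umol/L / 17.1 for bilirubin,
/ 88.4 for creatinine) numerically coincide with the score weights, so the
daily score in SI units reduces to 2.5*INR + bilirubin(umol/L) +
creatinine(umol/L).  The code converts explicitly and applies the printed
weights; the coincidence is documented, not exploited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, ValidationError

__all__ = [
    "BILIRUBIN_UMOL_PER_MGDL",
    "CREATININE_UMOL_PER_MGDL",
    "MHP_WEIGHTS",
    "MHP_SUM_CUTOFF",
    "HP_DAY3_CUTOFF",
    "DailyBloods",
    "HyderPawlikWeights",
    "HepaticaCoefficients",
    "bilirubin_umol_to_mgdl",
    "bilirubin_mgdl_to_umol",
    "creatinine_umol_to_mgdl",
    "creatinine_mgdl_to_umol",
    "impute_carry_forward",
    "modified_hp_daily",
    "modified_hp_sum",
    "hp_day3",
    "hepatica_score",
    "regeneration_score",
    "outcome_label",
    "score_cohort",
]

BILIRUBIN_UMOL_PER_MGDL = 17.1
CREATININE_UMOL_PER_MGDL = 88.4

#: weights of the modified Hyder-Pawlik daily score (INR, bilirubin mg/dL,
#: creatinine mg/dL)
MHP_WEIGHTS = (2.5, 17.1, 88.4)

#: strict cutoff on the 5-day sum discriminating poor outcome ("over 22")
MHP_SUM_CUTOFF = 22.0

#: strict cutoff on the day-3 Hyder-Pawlik score (">9")
HP_DAY3_CUTOFF = 9.0

POSTOP_DAYS = (1, 2, 3, 4, 5)
ANALYTES = ("inr", "bilirubin_mgdl", "creatinine_mgdl")


def bilirubin_umol_to_mgdl(x):
    return np.asarray(x, dtype=float) / BILIRUBIN_UMOL_PER_MGDL


def bilirubin_mgdl_to_umol(x):
    return np.asarray(x, dtype=float) * BILIRUBIN_UMOL_PER_MGDL


def creatinine_umol_to_mgdl(x):
    return np.asarray(x, dtype=float) / CREATININE_UMOL_PER_MGDL


def creatinine_mgdl_to_umol(x):
    return np.asarray(x, dtype=float) * CREATININE_UMOL_PER_MGDL


@dataclass(frozen=True)
class DailyBloods:
    """One post-operative day's bloods in scoring units (mg/dL)."""

    day: int
    inr: float
    bilirubin_mgdl: float
    creatinine_mgdl: float
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.day not in POSTOP_DAYS:
            raise ValidationError(f"day must be in 1..5, got {self.day}")
        for name in ("inr", "bilirubin_mgdl", "creatinine_mgdl"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class HyderPawlikWeights:
    """Weights of the day-3 Hyder-Pawlik score.

    The Clavien-Dindo weight is not fixed here; it must be supplied by
    configuration (it comes from the original publication, not from the
    blood-weight triple).
    """

    inr: float = 2.5
    bilirubin: float = 17.1
    creatinine: float = 88.4
    clavien_dindo: float | None = None


@dataclass(frozen=True)
class HepaticaCoefficients:
    """Printed coefficients of the Hepatica composite; overridable for refits."""

    intercept: float = 1.24
    beta_logflr: float = -2.26
    beta_ct1: float = 0.013


def impute_carry_forward(
    bloods: pd.DataFrame,
    allow_preop_fallback: bool = False,
) -> pd.DataFrame:
    """Complete a partial day-1..5 blood series by carrying values forward.

    ``bloods`` has columns ``day`` plus any of ``inr``, ``bilirubin_mgdl``,
    ``creatinine_mgdl``; rows for missing days may be absent or hold NaN.
    Each missing day takes the previous day's value.  A missing day 1 is
    an error unless ``allow_preop_fallback`` is set and a day-0 (pre-op)
    row is present to seed the carry.

    Returns a frame indexed 1..5 with per-analyte ``*_imputed`` flags and
    an overall ``imputed`` column.  Observed values are never altered.
    """
    df = bloods.copy()
    if "day" not in df.columns:
        raise ValidationError("bloods frame must have a 'day' column")
    analytes = [a for a in ANALYTES if a in df.columns]
    if not analytes:
        raise ValidationError(f"no analyte columns found (expected any of {ANALYTES})")
    df = df.set_index("day")
    if df.index.duplicated().any():
        raise ValidationError("duplicate days in blood series")

    days = [0, *POSTOP_DAYS] if allow_preop_fallback else list(POSTOP_DAYS)
    full = df.reindex(days)[analytes].astype(float)
    observed = full.notna()
    for a in analytes:
        if not observed.loc[1, a]:
            if not (allow_preop_fallback and observed.loc[0, a]):
                raise ValidationError(
                    f"day 1 {a} missing and no pre-op fallback enabled"
                )
        bad = full[a][full[a].notna() & (full[a] < 0)]
        if len(bad):
            raise ValidationError(f"negative {a} value in blood series")
    filled = full.ffill()
    out = filled.loc[list(POSTOP_DAYS)].copy()
    obs = observed.loc[list(POSTOP_DAYS)]
    for a in analytes:
        out[f"{a}_imputed"] = ~obs[a]
    out["imputed"] = ~obs[analytes].all(axis=1)
    if out[analytes].isna().any().any():
        raise ValidationError("blood series could not be completed")
    out.index.name = "day"
    return out


def modified_hp_daily(b: DailyBloods) -> float:
    """2.5*INR + 17.1*bilirubin(mg/dL) + 88.4*creatinine(mg/dL)."""
    w_inr, w_bil, w_cre = MHP_WEIGHTS
    return w_inr * b.inr + w_bil * b.bilirubin_mgdl + w_cre * b.creatinine_mgdl


def modified_hp_sum(series: list[DailyBloods]) -> float:
    """Sum of the daily modified scores over post-operative days 1-5."""
    days = sorted(b.day for b in series)
    if days != list(POSTOP_DAYS):
        raise ValidationError(
            f"series must cover days 1..5 exactly once (impute first); got {days}"
        )
    return float(sum(modified_hp_daily(b) for b in series))


def hp_day3(
    b: DailyBloods,
    clavien_dindo: int,
    weights: HyderPawlikWeights,
) -> float:
    """Day-3 Hyder-Pawlik score with Clavien-Dindo weighting.

    Scores above ``HP_DAY3_CUTOFF`` (strict) flag elevated 90-day
    mortality risk.
    """
    if b.day != 3:
        raise ValidationError(f"hp_day3 needs day-3 bloods, got day {b.day}")
    if not 0 <= int(clavien_dindo) <= 5:
        raise ValidationError("Clavien-Dindo grade must be in 0..5")
    if weights.clavien_dindo is None:
        raise ConfigurationError(
            "Clavien-Dindo weight not configured; supply HyderPawlikWeights "
            "with an explicit clavien_dindo value"
        )
    return (
        weights.inr * b.inr
        + weights.bilirubin * b.bilirubin_mgdl
        + weights.creatinine * b.creatinine_mgdl
        + weights.clavien_dindo * int(clavien_dindo)
    )


def hepatica_score(
    flr_percent: float,
    ct1_ms: float,
    coeffs: HepaticaCoefficients = HepaticaCoefficients(),
) -> float:
    """exp(-(intercept + ln(FLR%) * beta_logflr + cT1 * beta_ct1)).

    FLR enters in percent on the natural-log scale.  Higher scores mean
    lower risk: the score increases with FLR and decreases with cT1 at
    the default coefficients.
    """
    if not (np.isfinite(flr_percent) and flr_percent > 0):
        raise ValidationError(f"flr_percent must be > 0, got {flr_percent}")
    if not (np.isfinite(ct1_ms) and ct1_ms > 0):
        raise ValidationError(f"ct1_ms must be > 0, got {ct1_ms}")
    eta = (
        coeffs.intercept
        + math.log(flr_percent) * coeffs.beta_logflr
        + ct1_ms * coeffs.beta_ct1
    )
    return math.exp(-eta)


def regeneration_score(
    preop_volume_ml: float,
    followup_volume_ml: float,
    resected_volume_ml: float,
    mode: str = "caption",
) -> float:
    """Achieved-regeneration score at follow-up.

    mode 'caption': pre-operative volume divided by follow-up volume.
    mode 'resected-relative': fraction of the resected volume regrown,
    (followup - (preop - resected)) / resected — the form behind
    "regenerated at least 90% of the resected volume" statements.
    """
    for name, v in (
        ("preop_volume_ml", preop_volume_ml),
        ("followup_volume_ml", followup_volume_ml),
    ):
        if not (np.isfinite(v) and v > 0):
            raise ValidationError(f"{name} must be > 0")
    if resected_volume_ml < 0 or resected_volume_ml > preop_volume_ml:
        raise ValidationError("resected volume must be in [0, preop volume]")
    if mode == "caption":
        return preop_volume_ml / followup_volume_ml
    if mode == "resected-relative":
        if resected_volume_ml <= 0:
            raise ValidationError(
                "resected-relative mode needs a positive resected volume"
            )
        remnant = preop_volume_ml - resected_volume_ml
        return (followup_volume_ml - remnant) / resected_volume_ml
    raise ValidationError(f"unknown regeneration mode {mode!r}")


def outcome_label(
    mhp_sums,
    rule: str = "upper_quartile",
    cutoff: float = MHP_SUM_CUTOFF,
) -> np.ndarray:
    """Flag poor post-operative outcome across a cohort.

    rule 'threshold': sum strictly above ``cutoff`` (default 22).
    rule 'upper_quartile': sum strictly above the cohort's 75th percentile
    (linear interpolation between order statistics).
    """
    sums = np.asarray(mhp_sums, dtype=float)
    if rule == "threshold":
        return sums > cutoff
    if rule == "upper_quartile":
        if sums.size < 4:
            raise ValidationError("upper-quartile rule needs at least 4 patients")
        return sums > np.percentile(sums, 75)
    raise ValidationError(f"unknown outcome rule {rule!r}")


def _patient_bloods_mgdl(rows: pd.DataFrame) -> pd.DataFrame:
    post = rows[rows["day"].between(0, 5)]
    frame = pd.DataFrame(
        {
            "day": post["day"].astype(int),
            "inr": post["inr"].astype(float),
            "bilirubin_mgdl": bilirubin_umol_to_mgdl(post["bilirubin_umol_l"]),
            "creatinine_mgdl": creatinine_umol_to_mgdl(post["creatinine_umol_l"]),
        }
    )
    return frame[frame["day"] >= 1].reset_index(drop=True)


def score_cohort(
    cohort: pd.DataFrame,
    hp_weights: HyderPawlikWeights | None = None,
    hepatica_coeffs: HepaticaCoefficients = HepaticaCoefficients(),
    outcome_rule: str = "upper_quartile",
    outcome_cutoff: float = MHP_SUM_CUTOFF,
    regeneration_mode: str = "caption",
) -> pd.DataFrame:
    """Build the per-patient score panel from a long-format cohort table.

    Expects the :data:`hepaplan.volumetric_io.COHORT_COLUMNS` schema.
    hp_day3 is only computed when ``hp_weights`` carries a Clavien-Dindo
    weight; regeneration needs a follow-up visit (day >= 90).
    """
    panels = []
    for pid, rows in cohort.groupby("patient_id", sort=True):
        pre = rows[rows["day"] == -1]
        if len(pre) != 1:
            raise ValidationError(f"patient {pid!r}: expected one pre-op row")
        pre = pre.iloc[0]

        completed = impute_carry_forward(_patient_bloods_mgdl(rows))
        daily = [
            DailyBloods(
                day=int(d),
                inr=completed.loc[d, "inr"],
                bilirubin_mgdl=completed.loc[d, "bilirubin_mgdl"],
                creatinine_mgdl=completed.loc[d, "creatinine_mgdl"],
                imputed=bool(completed.loc[d, "imputed"]),
            )
            for d in POSTOP_DAYS
        ]
        mhp_days = {f"mhp_day{b.day}": modified_hp_daily(b) for b in daily}
        panel = {
            "patient_id": pid,
            **mhp_days,
            "mhp_sum": modified_hp_sum(daily),
            "any_imputed": bool(completed["imputed"].any()),
            "flr_percent": float(pre["flr_percent"]),
            "ct1_ms": float(pre["ct1_ms"]),
            "pdff_percent": float(pre["pdff_percent"]),
            "hepatica": hepatica_score(
                float(pre["flr_percent"]), float(pre["ct1_ms"]), hepatica_coeffs
            ),
        }

        if hp_weights is not None and hp_weights.clavien_dindo is not None:
            cd = rows.loc[rows["day"].between(0, 5), "clavien_dindo"].max()
            panel["hp_day3"] = hp_day3(daily[2], int(cd), hp_weights)
        else:
            panel["hp_day3"] = np.nan

        follow = rows[rows["day"] >= 90]
        preop_vol = float(pre["liver_volume_ml"])
        if len(follow) and np.isfinite(preop_vol):
            followup_vol = float(follow.iloc[0]["liver_volume_ml"])
            resected_ml = preop_vol * (1.0 - float(pre["flr_percent"]) / 100.0)
            panel["regeneration"] = regeneration_score(
                preop_vol, followup_vol, resected_ml, mode=regeneration_mode
            )
        else:
            panel["regeneration"] = np.nan
        panels.append(panel)

    out = pd.DataFrame(panels)
    out["outcome_poor"] = outcome_label(
        out["mhp_sum"].to_numpy(), rule=outcome_rule, cutoff=outcome_cutoff
    )
    return out
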