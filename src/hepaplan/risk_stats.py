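"""Statistical evaluation: stepwise-AIC logistic regression, ROC/AUROC
with DeLong variance and test, Youden threshold, collinearity (VIF) and
rank tests.

The AUROC and DeLong machinery are implemented from structural components
(placements) so the paired test shares its ingredients with the variance;
tests cross-check them against exhaustive pair counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._exceptions import ValidationError

__all__ = [
    "CANDIDATE_PREDICTORS",
    "PredictorMatrix",
    "build_predictor_matrix",
    "StepwiseResult",
    "stepwise_logistic_aic",
    "AurocResult",
    "auroc",
    "YoudenResult",
    "youden_threshold",
    "DeLongResult",
    "delong_test",
    "collinearity_check",
    "rank_tests",
]

#: the nine candidate pre-operative predictors, in canonical order.
#: ``log_flr`` is ln(FLR%) and ``ct1`` is in ms, matching the terms of the
#: composite-score formula.
CANDIDATE_PREDICTORS = (
    "age",
    "bmi",
    "creatinine",
    "bilirubin",
    "liver_volume",
    "lesion_volume",
    "log_flr",
    "liver_fat",
    "ct1",
)


@dataclass
class PredictorMatrix:
    """Per-patient candidate predictors, outcome flag and eligibility."""

    frame: pd.DataFrame
    outcome: np.ndarray
    eligible: np.ndarray

    def __post_init__(self) -> None:
        missing = set(CANDIDATE_PREDICTORS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"predictor matrix missing: {sorted(missing)}")
        self.outcome = np.asarray(self.outcome, dtype=bool)
        self.eligible = np.asarray(self.eligible, dtype=bool)
        if not (len(self.frame) == len(self.outcome) == len(self.eligible)):
            raise ValidationError("predictor matrix length mismatch")
        # rows with any missing candidate can never enter a fit
        complete = self.frame[list(CANDIDATE_PREDICTORS)].notna().all(axis=1).to_numpy()
        self.eligible = self.eligible & complete

    def design(self):
        X = self.frame.loc[self.eligible, list(CANDIDATE_PREDICTORS)].reset_index(
            drop=True
        )
        return X, self.outcome[self.eligible].astype(float)


def build_predictor_matrix(
    panel: pd.DataFrame,
    cohort_preop: pd.DataFrame,
    min_resected_fraction: float = 0.10,
) -> PredictorMatrix:
    """Assemble the nine-candidate matrix from score panel + pre-op rows.

    Eligibility: at least ``min_resected_fraction`` of the liver removed
    (inclusive) and complete candidate data.
    """
    pre = cohort_preop[cohort_preop["day"] == -1].set_index("patient_id")
    pan = panel.set_index("patient_id")
    ids = pan.index
    pre = pre.loc[ids]
    flr = pan["flr_percent"].to_numpy(dtype=float)
    frame = pd.DataFrame(
        {
            "age": pre["age_y"].to_numpy(dtype=float),
            "bmi": pre["bmi"].to_numpy(dtype=float),
            "creatinine": pre["creatinine_umol_l"].to_numpy(dtype=float),
            "bilirubin": pre["bilirubin_umol_l"].to_numpy(dtype=float),
            "liver_volume": pre["liver_volume_ml"].to_numpy(dtype=float),
            "lesion_volume": pre["lesion_volume_ml"].to_numpy(dtype=float),
            "log_flr": np.log(flr),
            "liver_fat": pan["pdff_percent"].to_numpy(dtype=float),
            "ct1": pan["ct1_ms"].to_numpy(dtype=float),
        },
        index=ids,
    ).reset_index()
    resected = 1.0 - flr / 100.0
    eligible = resected >= min_resected_fraction - 1e-9  # inclusive boundary
    return PredictorMatrix(
        frame=frame,
        outcome=pan["outcome_poor"].to_numpy(dtype=bool),
        eligible=eligible,
    )


@dataclass
class StepwiseResult:
    selected: tuple
    coefficients: dict
    aic: float
    trace: list = field(default_factory=list)
    separation_flag: bool = False
    n: int = 0


def _fit_logit(X: pd.DataFrame, y: np.ndarray, terms: tuple):
    design = sm.add_constant(X[list(terms)], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            return None
    return res


def stepwise_logistic_aic(
    X_in: "PredictorMatrix | pd.DataFrame",
    y: np.ndarray | None = None,
    candidates: tuple | None = None,
) -> StepwiseResult:
    """Bidirectional stepwise logistic regression minimising AIC.

    Starts from the intercept-only model; at every step the single
    add-or-drop move with the largest AIC improvement is taken; the search
    stops when no move improves AIC.  Fits are maximum-likelihood logistic
    regressions (IRLS as implemented by statsmodels).  Perfect separation
    is flagged and coefficients are reported at the convergence cap.
    """
    if isinstance(X_in, PredictorMatrix):
        X, y = X_in.design()
        candidates = candidates or CANDIDATE_PREDICTORS
    else:
        X = X_in.reset_index(drop=True)
        if y is None:
            raise ValidationError("outcome vector required")
        y = np.asarray(y, dtype=float)
        candidates = candidates or tuple(X.columns)

    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 < 2 or n0 < 2:
        raise ValidationError(
            f"need >= 2 eligible patients per outcome class (got {n1}/{n0})"
        )

    current: tuple = ()
    base = _fit_logit(X, y, current)
    if base is None:
        raise ValidationError("intercept-only logistic fit failed")
    best_aic = base.aic
    best_res = base
    trace = [{"terms": current, "aic": float(best_aic)}]
    separation = False

    while True:
        moves = []
        for term in candidates:
            if term in current:
                moves.append(tuple(t for t in current if t != term))
            else:
                moves.append(current + (term,))
        best_move = None
        for terms in moves:
            res = _fit_logit(X, y, terms)
            if res is None:
                continue
            if not res.mle_retvals.get("converged", True):
                separation = True
            if res.aic < best_aic - 1e-9:
                if best_move is None or res.aic < best_move[1]:
                    best_move = (terms, res.aic, res)
        if best_move is None:
            break
        current, best_aic, best_res = best_move
        trace.append({"terms": current, "aic": float(best_aic)})

    coefs = dict(zip(best_res.params.index, map(float, best_res.params)))
    return StepwiseResult(
        selected=tuple(current),
        coefficients=coefs,
        aic=float(best_aic),
        trace=trace,
        separation_flag=separation,
        n=len(y),
    )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValidationError("both outcome classes must be present")
    return labels


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components: per-positive and per-negative
    placements (ties count one half)."""
    pos = scores[labels]
    neg = scores[~labels]
    # pairwise comparison; sizes here are cohort-scale so O(n1*n0) is fine
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    psi = gt + 0.5 * eq
    v10 = psi.mean(axis=1)  # one per positive
    v01 = psi.mean(axis=0)  # one per negative
    return v10, v01


@dataclass(frozen=True)
class AurocResult:
    auc: float
    variance: float
    ci_lo: float
    ci_hi: float
    n_pos: int
    n_neg: int


def auroc(scores, labels, alpha: float = 0.05) -> AurocResult:
    """AUROC with DeLong variance and a logit-scale Wald CI.

    The AUC equals the Mann-Whitney U statistic normalised by n1*n0 with
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    v10, v01 = _delong_placements(scores, labels)
    auc = float(v10.mean())
    n1, n0 = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    if 0.0 < auc < 1.0 and var > 0:
        logit = np.log(auc / (1 - auc))
        se_logit = np.sqrt(var) / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
        hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    else:  # degenerate AUC; fall back to clipped linear Wald
        half = z * np.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return AurocResult(auc, float(var), float(lo), float(hi), n1, n0)


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_threshold(scores, labels) -> YoudenResult:
    """Threshold maximising sensitivity + specificity - 1.

    Prediction is positive when score >= threshold.  Candidates are the
    midpoints between consecutive unique scores plus sentinels below and
    above the range; ties in J break toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])

    best = None
    for thr in candidates:
        pred = scores >= thr
        sens = np.mean(pred[labels])
        spec = np.mean(~pred[~labels])
        j = sens + spec - 1.0
        key = (j, spec, thr)
        if best is None or key > (best.youden_j, best.specificity, best.threshold):
            best = YoudenResult(float(thr), float(sens), float(spec), float(j))
    return best


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's test for two correlated ROC curves (two-sided).

    Identical or monotone-equivalent score pairs have equal placements,
    hence z = 0 and p = 1; a zero-variance difference with unequal AUCs
    is an error.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(np.asarray(labels))
    if scores_a.shape != scores_b.shape or len(scores_a) != len(labels):
        raise ValidationError("paired scores must cover the same patients")

    v10a, v01a = _delong_placements(scores_a, labels)
    v10b, v01b = _delong_placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    n1, n0 = len(v10a), len(v01a)
    if n1 < 2 or n0 < 2:
        raise ValidationError("need >= 2 patients per class for DeLong variance")

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / n1 + s01 / n0
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        if abs(diff) <= 1e-12:
            return DeLongResult(auc_a, auc_b, 0.0, 1.0)
        raise ValidationError("degenerate variance of the AUC difference")
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(z), float(p))


def collinearity_check(
    X: pd.DataFrame, vif_cap: float = 10.0
) -> pd.DataFrame:
    """Variance-inflation factor per predictor from auxiliary regressions.

    A constant column gets an infinite VIF and is flagged.
    """
    X = X.reset_index(drop=True).astype(float)
    cols = list(X.columns)
    rows = []
    for col in cols:
        y = X[col].to_numpy()
        if np.ptp(y) == 0:
            rows.append({"predictor": col, "vif": np.inf, "flagged": True})
            continue
        others = [c for c in cols if c != col]
        A = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": col, "vif": float(vif), "flagged": vif > vif_cap})
    return pd.DataFrame(rows)


def rank_sum_test(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum.

    Exact enumeration when both groups have <= 10 members and no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 members")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def rank_tests(
    cohort_wide: pd.DataFrame,
    ct1_threshold_ms: float = 795.0,
    min_resected_fraction: float = 0.10,
) -> dict:
    """Length-of-stay rank-sum split on cT1, plus histology correlations.

    ``cohort_wide`` needs per-patient columns ``ct1_ms``, ``flr_percent``,
    ``los_days``, ``nas_ballooning``, ``nas_inflammation``,
    ``nas_steatosis``, ``pdff_percent``.  The LOS comparison is restricted
    to patients with at least ``min_resected_fraction`` of the liver
    removed.
    """
    df = cohort_wide
    eligible = (1.0 - df["flr_percent"] / 100.0) >= min_resected_fraction - 1e-9
    sub = df[eligible]
    hi = sub[sub["ct1_ms"] > ct1_threshold_ms]["los_days"].dropna()
    lo = sub[sub["ct1_ms"] <= ct1_threshold_ms]["los_days"].dropna()
    out: dict = {"n_eligible": int(eligible.sum())}
    out["wilcoxon_los"] = {
        **rank_sum_test(hi.to_numpy(), lo.to_numpy()),
        "n_high_ct1": int(len(hi)),
        "n_normal_ct1": int(len(lo)),
        "median_high": float(np.median(hi)),
        "median_normal": float(np.median(lo)),
    }

    pairs = {
        "ct1_vs_ballooning": ("ct1_ms", "nas_ballooning"),
        "ct1_vs_inflammation": ("ct1_ms", "nas_inflammation"),
        "pdff_vs_steatosis": ("pdff_percent", "nas_steatosis"),
    }
    spearman = {}
    for name, (a, b) in pairs.items():
        sel = df[[a, b]].dropna()
        rho, p = stats.spearmanr(sel[a], sel[b])
        spearman[name] = {"rho": float(rho), "p": float(p), "n": int(len(sel))}
    out["spearman"] = spearman
    return out
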