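"""End-to-end orchestration: phantom -> segmentation -> plan -> FLR,
cohort -> scores -> model report.  All randomness flows from one seed and
outputs are written deterministically (fixed float formats, sorted keys).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import couinaud, parenchyma, resection_flr, risk_stats, scores, synthetic_data
from ._exceptions import ValidationError
from .config import PipelineConfig
from .volumetric_io import write_landmarks, write_volume

logger = logging.getLogger("hepaplan")

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _roc_points(score_values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-score_values, kind="stable")
    s, y = score_values[order], labels[order].astype(bool)
    thresholds, sens, spec = [], [], []
    n1, n0 = y.sum(), (~y).sum()
    for thr in np.unique(s)[::-1]:
        pred = score_values >= thr
        thresholds.append(thr)
        sens.append((pred & labels).sum() / n1)
        spec.append((~pred & ~labels).sum() / n0)
    return pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )


def run_pipeline(config: PipelineConfig, outdir: Path) -> dict:
    """Run the full demo pipeline into ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"seed": config.seed, "outputs": [], "thresholds": vars(config.thresholds)}

    try:
        # --- stage 1: phantom geometry -----------------------------------
        logger.info("stage=phantom spacing=%s", config.phantom_spacing_mm)
        phantom = synthetic_data.make_phantom(
            spacing_mm=(config.phantom_spacing_mm,) * 3,
            tumours=[{"id": "t1", "centre_mm": (35.0, -20.0, 10.0), "radius_mm": 8.0}],
        )
        write_volume(phantom.liver, outdir / "phantom_liver.nii.gz")
        write_landmarks(phantom.landmarks, outdir / "phantom_landmarks.csv")

        planes = couinaud.build_planes(phantom.landmarks)
        labels = couinaud.label_segments(
            phantom.liver, planes, caudate_radius_mm=config.thresholds.caudate_radius_mm
        )
        seg_df = couinaud.segment_volumes(labels)
        _write_csv(seg_df, outdir / "segment_volumes.csv")
        write_volume(labels, outdir / "phantom_segments.nii.gz")

        plan = resection_flr.ResectionPlan(
            segments_removed=frozenset({6, 7}),
            wedges=(resection_flr.WedgeSpec(tumour_id="t1", margin_mm=5.0),),
        )
        flr_res = resection_flr.apply_plan(phantom.liver, labels, phantom.tumours, plan)
        write_volume(flr_res.remnant_mask, outdir / "phantom_remnant.nii.gz")
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "flr_percent": flr_res.flr_percent,
                        "resected_volume_ml": flr_res.resected_volume_ml,
                        "total_parenchyma_ml": flr_res.total_parenchyma_ml,
                        "lesion_volume_ml": flr_res.lesion_volume_ml,
                    }
                ]
            ),
            outdir / "phantom_flr.csv",
        )
        logger.info("stage=phantom flr=%.2f%%", flr_res.flr_percent)

        # --- stage 2: synthetic cohort + scores --------------------------
        cp = config.cohort
        cohort = synthetic_data.synthetic_cohort(
            cp.n,
            effect=synthetic_data.CohortEffect(cp.beta0, cp.beta_logflr, cp.beta_ct1),
            blood_noise=cp.blood_noise,
            missing_day_prob=cp.missing_day_prob,
            regen_link=cp.regen_link,
            regen_noise=cp.regen_noise,
            seed=config.seed,
        )
        _write_csv(cohort, outdir / "cohort.csv")

        hp_weights = None
        if config.clavien_dindo_weight is not None:
            hp_weights = scores.HyderPawlikWeights(
                clavien_dindo=config.clavien_dindo_weight
            )
        panel = scores.score_cohort(
            cohort,
            hp_weights=hp_weights,
            outcome_rule=config.thresholds.outcome_rule,
            outcome_cutoff=config.thresholds.mhp_sum_cutoff,
        )
        panel["ct1_class"] = [
            parenchyma.classify_ct1(v, config.thresholds.ct1_elevated_ms)
            for v in panel["ct1_ms"]
        ]
        _write_csv(panel, outdir / "score_panel.csv")
        logger.info("stage=scores n=%d poor=%d", len(panel), int(panel["outcome_poor"].sum()))

        # --- stage 3: statistical evaluation -----------------------------
        pre = synthetic_data.preop_table(cohort)
        pm = risk_stats.build_predictor_matrix(
            panel, pre, min_resected_fraction=config.thresholds.min_resected_fraction
        )
        step = risk_stats.stepwise_logistic_aic(pm)
        X, y = pm.design()
        ybool = y.astype(bool)
        hep = panel.set_index("patient_id").loc[
            pm.frame.loc[pm.eligible, "patient_id"], "hepatica"
        ].to_numpy()
        # low composite score and low FLR both mean high risk: negate so
        # larger predictor values track poor outcome
        risk_comp = -hep
        risk_flr = -np.exp(X["log_flr"].to_numpy())
        auc_comp = risk_stats.auroc(risk_comp, ybool)
        auc_flr = risk_stats.auroc(risk_flr, ybool)
        delong = risk_stats.delong_test(risk_comp, risk_flr, ybool)
        youden = risk_stats.youden_threshold(risk_comp, ybool)
        vif = risk_stats.collinearity_check(
            X[list(risk_stats.CANDIDATE_PREDICTORS)], vif_cap=config.thresholds.vif_cap
        )
        ranks = risk_stats.rank_tests(
            pre,
            ct1_threshold_ms=config.thresholds.ct1_elevated_ms,
            min_resected_fraction=config.thresholds.min_resected_fraction,
        )

        # composite risk increases as the score falls, so rank by -score
        roc = _roc_points(-hep, ybool)
        _write_csv(roc, outdir / "roc_points.csv")
        _write_csv(vif, outdir / "vif.csv")

        report = {
            "n_eligible": int(pm.eligible.sum()),
            "stepwise": {
                "selected": list(step.selected),
                "coefficients": step.coefficients,
                "aic": step.aic,
                "aic_trace": [
                    {"terms": list(t["terms"]), "aic": t["aic"]} for t in step.trace
                ],
                "separation_flag": step.separation_flag,
            },
            "auroc_composite": {
                "auc": auc_comp.auc, "ci": [auc_comp.ci_lo, auc_comp.ci_hi]
            },
            "auroc_flr_alone": {
                "auc": auc_flr.auc, "ci": [auc_flr.ci_lo, auc_flr.ci_hi]
            },
            "delong": {"z": delong.z, "p": delong.p},
            "youden": {
                "threshold": youden.threshold,
                "sensitivity": youden.sensitivity,
                "specificity": youden.specificity,
            },
            "rank_tests": ranks,
        }
        _write_json(report, outdir / "model_report.json")
        _plot_roc(roc, auc_comp.auc, outdir / "roc.png")
        logger.info(
            "stage=fit selected=%s auc=%.3f", step.selected, auc_comp.auc
        )

        for p in sorted(outdir.iterdir()):
            if p.name != "manifest.json":
                manifest["outputs"].append(p.name)
        _write_json(manifest, outdir / "manifest.json")
        return manifest
    except ValidationError:
        logger.exception("pipeline stage failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _plot_roc(roc: pd.DataFrame, auc: float, path: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1 - roc["specificity"], roc["sensitivity"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"Composite score ROC (AUC = {auc:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
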