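# hepaplan

Pre-operative liver-performance analysis as a tested Python pipeline:

- **Couinaud segmentation** of a binary liver mask from eight named
  anatomical landmarks (IVC inferior/superior, right/middle/left hepatic
  veins, gallbladder fossa, umbilical fissure, left/right portal vein),
  via oriented cutting planes in scanner-mm space.
- **Virtual hepatectomy**: remove named segments and/or conical-frustrum
  wedge resections and compute the planned future liver remnant (FLR) as
  a parenchymal fraction.
- **Quantitative-map summaries** (cT1 / PDFF / T2*) over liver regions
  with lesion exclusion and the 795 ms cT1 upper-limit-of-normal
  classification.
- **Scores**: daily and 5-day-summed modified Hyder-Pawlik score
  (2.5·INR + 17.1·bilirubin[mg/dL] + 88.4·creatinine[mg/dL]) with
  carry-forward imputation of incomplete blood series, the day-3
  Hyder-Pawlik score, the composite risk score
  `exp(-(1.24 + ln(FLR%)·(-2.26) + cT1·0.013))`, achieved-regeneration
  scoring, and cohort outcome labelling (sum > 22 or upper quartile).
- **Statistics**: bidirectional stepwise-AIC logistic regression over
  nine pre-operative candidates, AUROC with DeLong variance and the
  paired DeLong test, Youden threshold, VIF collinearity check,
  Wilcoxon rank-sum (exact for small groups) and Spearman correlations.
- **Synthetic data**: analytic ellipsoid liver phantoms with closed-form
  per-segment volumes, and cohort generators matched to target
  median/IQR distributions with a logistic outcome model on
  (ln FLR, cT1) — so every stage runs with no external data.

## CLI

```sh
hepaplan simulate --n 200 --seed 1 --outdir out/sim
hepaplan segment  --liver out/sim/phantom_liver.nii.gz \
                  --landmarks out/sim/phantom_landmarks.csv --outdir out/seg
hepaplan plan     --liver out/sim/phantom_liver.nii.gz \
                  --labels out/seg/segments.nii.gz \
                  --plan plan.json --outdir out/plan
hepaplan score    --cohort out/sim/cohort.csv --outdir out/scored
hepaplan fit      --cohort out/sim/cohort.csv \
                  --panel out/scored/score_panel.csv --outdir out/fit
hepaplan run      --seed 1 --outdir out/run        # full demo pipeline
```

`hepaplan run` accepts `--config config.yaml` capturing every threshold
(795 ms cT1 limit, the >22 sum cutoff, the >9 day-3 cutoff, the outcome
rule, the ≥10% resected-fraction filter, the VIF cap, the caudate
radius) and all generator knobs; see `hepaplan.config.PipelineConfig`.
Re-running with the same config and seed reproduces every CSV/JSON
output byte for byte.

A resection plan file is JSON, e.g.

```json
{"segments_removed": [6, 7],
 "wedges": [{"tumour_id": "t1", "margin_mm": 10.0}]}
```

## Data formats

- Volumes: NIfTI-1/2 (`.nii` / `.nii.gz`); masks are {0,1}, label maps
  integers 1–8, quantitative maps float (NaN = unmapped).
- Landmarks: CSV with columns `name,x_mm,y_mm,z_mm` (scanner mm).
- Cohort: long-format CSV, one row per patient-visit (`day` −1 pre-op,
  1–5 post-op, ≥90 follow-up); bilirubin/creatinine in µmol/L, converted
  internally to mg/dL for scoring.
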