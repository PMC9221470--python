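# melrad

Whole-body baseline-CT radiomics combined with clinical parameters to
predict three-month therapy response and six-/twelve-month overall survival
in stage-IV melanoma patients under first-line immunotherapy (PD-1 +/-
CTLA-4 checkpoint inhibition).

Real registry cohorts of this kind (hundreds of patients, thousands of
manually segmented metastases) are not publicly depositable, so the package
ships a calibrated synthetic-cohort generator and exercises the entire
analysis end to end on it. Every stage also accepts external data in the
documented CSV/NIfTI formats.

## What the pipeline computes

1. **Per-lesion radiomics.** For each segmented lesion, 14 shape features,
   plus 18 first-order and 75 texture features (GLCM, GLRLM, GLSZM, GLDM,
   NGTDM) on the original image, on Laplacian-of-Gaussian filtered images at
   sigma = 1...5 mm, and on the 8 sub-bands of a single-level stationary 3-D
   wavelet transform: 14 + 93 x 14 = **1316 features per lesion**.
2. **Patient-level aggregation.** Four schemes per feature — value of the
   largest lesion, volume-weighted mean of the three largest, value of the
   most predictive lesion, volume-weighted mean of the three most
   predictive (organ predictiveness: liver > adrenal gland/heart/spleen >
   skeletal > lung > lymph nodes > soft tissue/skin) — plus 20 tumour-burden
   features (lesion count and total volume, overall and per organ):
   4 x 1316 + 20 = **5284 features per patient**.
3. **Models.** Per endpoint e (response at 3 months with CR/PR = 1, SD/PD = 0;
   survival at 6 and at 12 months), two extremely randomized forests are
   compared in 10 x 5-fold repeated cross-validation: a *baseline* model on
   the clinical covariates only and an *extended* model on clinical
   covariates + an FCBF-selected radiomic subset. Preprocessing (ordinal
   encoding, imputation — 0.5 for binary, median otherwise — and
   z-normalization) and the FCBF filter are fitted per training fold only.
4. **FCBF selection.** Features are discretized to {-1, 0, 1} at +-0.5 and
   scored by symmetrical uncertainty SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y));
   a feature is dropped when a more class-relevant feature predominates it,
   SU(p, q) >= SU(q, class).
5. **Evaluation.** Out-of-fold scores are pooled per repetition into one
   ROC AUC; the point estimate is the mean over the R = 10 repetitions and
   the 95% CI is a patient-level percentile bootstrap (B = 1000) of that
   mean, with identical resamples shared by the models under comparison.
   Models differ significantly when their CIs do not overlap; a model is
   predictive when its CI lower bound exceeds 0.5. A bootstrap mean ROC
   curve with 95% band is computed on a fixed FPR grid.
6. **Risk stratification.** The 12-month-survival scores of repetition 0
   split the cohort at 0.5 into low-/high-risk groups, compared with
   Kaplan-Meier curves and a log-rank test.

## Worked example

```bash
melrad all --out-dir demo_run --seed 3 --n-patients 40 \
    --lesion-count-scale 0.1 --no-wavelet --no-log -R 2 -K 3 -B 60
python - << 'EOF'
import pandas as pd
r = pd.read_csv("demo_run/auc_report.csv")
print(r[r.model.isin(["baseline","extended"])][
    ["endpoint","model","auc","ci_low","ci_high","n_patients"]].to_string(index=False))
EOF
```

prints (40 synthetic patients, reduced lesion load, 107-feature schema,
2 x 3-fold CV, B = 60 — a smoke-scale configuration):

```
    endpoint    model      auc   ci_low  ci_high  n_patients
response_3mo baseline 0.429924 0.213450 0.609601        35.0
response_3mo extended 0.709280 0.585872 0.844478        35.0
    surv_6mo baseline 0.659722 0.569554 0.799506        37.0
    surv_6mo extended 0.576389 0.480000 0.703676        37.0
   surv_12mo baseline 0.470833 0.337373 0.587744        32.0
   surv_12mo extended 0.648958 0.503223 0.797918        32.0
```

Each row is one model on one endpoint: the mean pooled AUC over CV
repetitions with its bootstrap 95% CI and the number of patients whose
endpoint was known. At this toy scale the CIs are wide and the two models'
intervals overlap on every endpoint — with the default (weak) planted
effects no significant difference is expected, only the tendency of the
extended model to pick up the planted radiomic factor.
The run directory additionally holds the per-lesion and per-patient feature
tables, per-fold FCBF selection logs, ROC curve tables, Kaplan-Meier tables
and a log-rank summary for the risk groups, all stamped with a hash of the
run configuration.

Library use mirrors the CLI:

```python
from melrad import GeneratorConfig, generate_cohort, RunConfig, run_pipeline
```

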