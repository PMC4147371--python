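# msimetab

Multiplexed CE-MS metabolomics for exercise/glucose-tolerance studies:
simulation, signal processing, feature curation, OGTT analytics and
prognostic modelling.

## The problem

Multi-segment injection capillary electrophoresis–mass spectrometry
(MSI-CE-MS) injects seven sample plugs serially into one capillary, so each
metabolite shows up as up to seven time-ordered peaks in a single run. This
makes it possible to profile a subject's entire oral glucose tolerance test
(OGTT: blood draws at 0, 20, 30, 60, 90, 120 min) plus a pooled quality
control in one separation. In a repeated-measures cross-over design —
each subject tested before ("naive") and after ("trained") an exercise
intervention — the workflow yields a samples × metabolites matrix from
which one can classify plasma features modulated by post-prandial glucose
or training, and fit a regression predicting each subject's change in
glucose tolerance (Δ2hPG, the trained-minus-naive change in 2-h post-load
glucose) from baseline metabolites.

`msimetab` implements that whole chain as a tested, reusable library. Since
no raw study data are public, the package ships a seeded synthetic-data
generator that emulates the study conditions (11 subjects × 6 timepoints ×
2 states, one QC per run, ~55 authentic features among contaminants, junk
and redundant satellite ions, QC replicate CV ≈ 14%), so every downstream
stage is exercised end to end. The per-subject cohort endpoints table is
packaged, and the cohort-level statistics are recomputed from it exactly.

## What's inside

| module | role |
| --- | --- |
| `study_design` | factorial design → 7-segment runs; packaged cohort table |
| `synthetic` | seeded generator: responses, glucose curves, raw ion traces |
| `processing` | EIC extraction, peak picking, plug assignment, IS normalization (RMT/RPA), redundancy rejection |
| `feature_qc` | dilution trend filter (CV < 40%, R² > 0.90, ≥3 levels, silent blank) and study filter (75% detection, QC CV < 40%) |
| `glucose` | FG / 2hPG / trapezoidal tAUC, cohort deltas, paired t, Grubbs, responder taxonomy |
| `stats_suite` | log₁₀ + autoscale, RM two-way ANOVA + Bonferroni, paired volcano, ROC/AUC, NIPALS PLS-DA (VIP, LOO Q²), PCA, Ward HCA |
| `prognostic` | baseline predictor panels, OLS, LOOCV Q², forward stepwise selection |
| `pipeline` / `cli` | `msimetab simulate / process / analyze / report` |

The statistics at the core are written from first principles (NIPALS
component extraction, the VIP identity `mean(VIP²) = 1`, rank-based
AUC = U/(n₁n₂) with tie-corrected Mann–Whitney p, Q² = 1 − PRESS/TSS under
leave-one-out refitting, forward selection on Q²); scipy/statsmodels/numpy
handle the standard numerics underneath, and sklearn/pingouin appear only
as independent cross-checks in the test suite.

## Worked example

Simulate a small noise-free study, invert the raw traces, and analyze:

```bash
cat > cfg.yaml <<EOF
seed: 7
n_subjects: 4
n_features: 20
baseline_sd: 0.0
max_vars: 3
EOF
msimetab simulate --config cfg.yaml --out data
msimetab process  --config cfg.yaml --dataset data
msimetab analyze  --config cfg.yaml \
    --matrix data/processed/feature_matrix.csv \
    --glucose data/glucose.csv --out analysis
msimetab report --summary analysis/summary.json
```

The process step logs the feature-count narrowing through the two-stage
screen — 39 raw features (20 authentic + 8 blank contaminants + 8
dilution-independent junk + 3 redundant satellites) down to exactly the
authentic 20:

```
process: 39 raw features detected
process: dilution trend filter kept 23 / 39 features
process: redundancy rejection kept 36 / 39 features
process: study filter kept 20 / 20 features
process: mean QC CV 0.135
```

and the report digest prints:

```
Cohort:
  mean d_vo2max: +4.76
  mean d_wmax: +25.6
  mean d_fg: -0.236
  mean d_p2hg: -0.0545
  mean d_tauc: -8.4
  responders: {'positive': 6, 'non_responder': 3, 'negative': 2}
ANOVA significant (time/training): 8/0
Prognostic model: 2 variables, R2=0.964, Q2=0.219
```

The cohort block is the packaged 11-subject table: the mean VO₂max gain is
+4.8 mL/kg/min, fasting glucose fell 0.24 mM on average, and thresholding
Δ2hPG at ±0.5 mM splits the cohort into 6 positive / 3 non- / 2 negative
responders. The ANOVA line counts synthetic features significant after
Bonferroni for the post-prandial time course vs training status; the
prognostic line is the stepwise regression of simulated Δ2hPG on baseline
metabolite variables (a 4-subject toy cohort, hence the modest Q²).

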