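# Methods

## Study design model

The design is a repeated-measures cross-over: each subject completes an
oral glucose tolerance test (OGTT; 75 g glucose, blood at 0, 20, 30, 60,
90, 120 min) in the untrained ("naive") state and again after a six-week
high-intensity interval-training block ("trained"). The resting draw is
the 0-min sample, so six timepoints per test. With 11 subjects this gives
11 × 6 × 2 = 132 plasma samples.

Runs follow the seven-segment multiplexed injection format: the six OGTT
samples of one subject-state share one run (segments 1–6) and a pooled QC —
an equal-volume pool of all study plasma — occupies segment 7 of every run,
so 22 runs carry 22 QCs. Designs whose sample count is not divisible by six
pad the final run with blank segments, recorded on the manifest. Manifest
generation is deterministic (subject-major, naive before trained,
time-minor).

## Signal model and its inversion

The generator renders each metabolite as Gaussian peaks on an ion channel
at its m/z. The internal standard (Cl-Tyr, m/z 216.042, in every plug
including blanks) migrates at `t_IS + k·δ` for plug k, with `t_IS` 1100 s
and plug spacing δ = 25 s, so seven peaks span about three minutes. An
analyte with relative migration time RMT migrates at `RMT · (t_IS + k·δ)` —
the whole plug pattern scales with analyte mobility, which is what makes
per-segment normalization cancel drift. Peak area is `response · A_IS`, so
the relative peak area (RPA = analyte area / IS area, same segment)
recovers the planted response, and RMT (analyte apex / IS apex, same
segment) recovers the planted migration ratio exactly. A global drift
multiplier on all migration times leaves RMT invariant (tested at +5%).

Defaults: peak σ = 2 s, 2 Hz sampling over 400–1900 s, additive Gaussian
baseline noise (SD 100 counts; 0 in the noise-free tests), multiplicative
mean-one lognormal response noise. Redundant satellite ions (¹³C isotope
+1.00336, sodium adduct +21.98194, −NH₃, −H₂O) co-migrate with their parent
at a fixed area fraction on their own channel.

Inversion proceeds: extracted-ion trace (±10 ppm sum) → local maxima above
300 counts and S/N ≥ 3 inside the 480–1800 s window (salt front and
electroosmotic-flow regions excluded) → train splitting → plug assignment →
per-segment IS normalization. S/N uses the baseline SD estimated from
points below the 20th intensity percentile. Peak area is trapezoidal
between flanking local minima, additionally capped at ±4σ of the peak
(σ from the half-height width) so a neighbouring train's tail is not swept
in.

Two numerical choices deserve note:

* **Train splitting.** Isobaric metabolites (Leu/Ile at m/z 132.102) share
  a channel, each contributing its own seven-peak train; the trains
  interleave. The earliest unclaimed peak anchors a train, its apparent RMT
  predicts the remaining plug positions, and unclaimed peaks within 20% of
  the scaled plug spacing join. The gap-based segment assignment then runs
  per train. Feature identity is therefore keyed by m/z *and*
  RMT cluster (gap threshold 0.004), not m/z alone.
* **Residual cross-talk.** Where adjacent trains overlap (planted Leu–Ile
  spacing ≈ 8.7 s ≈ 4.4σ), valley-bounded integration exchanges ~1–2% of
  area between neighbours. Noise-free round-trip recovery is <1% on
  resolved channels and tested at 2.5% on the shared channel. Anything
  needing better would fit a peak model, which is out of scope here.
* **Anchoring.** The earliest peak of a train is assumed to be plug 1; a
  blank in segment 1 would shift labels by one. Study and dilution layouts
  never blank segment 1.

## Feature curation

Stage one, the dilution trend filter, is the untargeted primary screen run
on triplicate seven-segment dilution series of pooled plasma (levels 1,
1/2, …, 1/32, blank). A feature passes only if: no blank signal; ≥3
detected non-blank levels; replicate CV at the undiluted level < 40%
(strict); linearity R² of mean response vs dilution factor > 0.90
(unweighted least squares, not through zero). The verdict's reason names
the first failed criterion in that order. Stage two retains features
detected (non-missing RPA; no imputation before filtering) in ≥75% of
study samples — QC rows excluded from the denominator — with CV across the
pooled QCs < 40%. Redundant satellites are removed between the stages:
co-migrating features (|ΔRMT| ≤ 0.01) whose m/z offset matches the
satellite library within 10 ppm keep only their highest-response member.

On a zero-noise synthetic universe (authentic panel + blank contaminants +
dilution-independent junk + satellites) the chain recovers exactly the
authentic panel; this is the package's strongest end-to-end test.

## Glucose metrics and cohort arithmetic

FG = glucose at 0 min, 2hPG = glucose at 120 min, tAUC = trapezoidal area
0–120 min (mM·min). Cohort changes are trained-minus-naive; summaries use
the arithmetic mean and sample SD (n−1). The paired t-test is the
one-sample t on differences with a two-tailed Student-t p (cross-checked
against direct numerical integration of the t density to 1e−6 over
df 2–29). The Grubbs outlier test is the standard two-sided single-outlier
form, G = max|xᵢ−x̄|/s against the t-based critical value. Responder calls
on Δ2hPG use symmetric ±0.5 mM thresholds by default (positive ≤ −0.5,
negative ≥ +0.5; the threshold is a config knob since the non-response band is a
study-level judgement call).

## Statistical battery

* **Transform.** Missing/non-positive cells take half the feature's
  minimum positive value (recorded), then log₁₀, then per-feature centring
  and unit sample-SD (n−1) scaling.
* **RM two-way ANOVA.** Both factors (time, 6 levels; training, 2) are
  within-subject; each main effect tests against its subject×factor
  interaction and the time×training interaction against the three-way
  residual. Vectorized across features; degenerate (constant) features
  yield p = 1 rather than errors. Agrees with pingouin's two-way
  repeated-measures ANOVA to 1e−9 on shared inputs. Bonferroni multiplies
  by the number of features tested (per effect) and caps at 1; effect
  directions are reported only when the adjusted p clears α.
* **Volcano.** Fold change is the ratio of raw group means (the
  mean-of-paired-ratios alternative was the open question; ratio of means
  is the documented choice); p is a paired t on log values; significance
  needs FC outside [1/1.5, 1.5] and p < 0.05.
* **ROC.** AUC = U/(n₁n₂) with ties counted ½, oriented ≥ 0.5; p from the
  tie-corrected normal approximation to Mann–Whitney U without continuity
  correction. Exactly equal to brute-force pair counting (property-tested
  for all group sizes ≤ 8).
* **PLS-DA.** NIPALS extraction on the autoscaled matrix against a centred
  dummy-coded class label; R²Y is cumulative explained label variance; Q²
  refits the model (including centring) on every leave-one-out fold.
  VIP uses the standard weighted-loadings formula; mean squared VIP = 1 is
  an identity and is asserted. With components = rank the fit equals OLS;
  both checked against sklearn.
* **PCA/HCA.** SVD scores with explained-variance fractions; Ward linkage
  on Euclidean distances (common defaults in metabolomics practice), leaf order deterministic, exportable as Newick.

## Prognostic regression

Predictors come from the naive state at the anchor timepoints: per
candidate feature, log₁₀ response at 0 min, at 120 min, and their
log-ratio; named ratiometric markers add a log-ratio column per timepoint.
Note the three per-feature variables are exactly collinear in log space
(ratio = difference); the selection step simply skips rank-deficient
additions. Constant columns drop with a warning.

Selection is forward stepwise maximizing leave-one-out Q² = 1 − PRESS/TSS
(R² is monotone in variable count and cannot drive a stop rule), stopping
at no improvement or `max_vars` (default 8), ties broken lexicographically
so selection is deterministic and column-order invariant. The final model
is OLS with per-coefficient two-sided t-tests; a near-saturation warning
fires when rows − columns < 3. LOOCV refits use plain least squares for
speed; the reported coefficients/p-values come from the statsmodels fit.

## Synthetic-data conditions and what the tests show

Generator defaults are the study conditions: 11×6×2 design, 55-feature
authentic panel (20 named metabolites with the observed effect directions —
amino acids and urea-cycle/carnitine intermediates declining ~15–40% over
the 2-h curve, disulfides declining ~22–25% with training, ornithine
responding to both — plus unnamed fillers), biological CV 20%, analytical
CV 14% (which reproduces the ~14% mean QC CV over 22 simulated QCs), and a
planted linear model tying Δ2hPG to three standardized baseline predictors
(betas 0.8, 0.6, −0.5 mM/SD, residual SD 0.1 mM). Glucose curves rise
smoothly from a fasting value to a subject-specific peak at 20–60 min and
relax toward the 120-min value; the trained curve's endpoint carries the
planted Δ2hPG.

What passing tests do and do not show: the generator's Gaussian peaks,
lognormal noise and clean factorial layout are far kinder than real
electropherograms (no tailing, no co-migration beyond the planted isobars,
no missing visits, no batch drift beyond a global multiplier), so
end-to-end recovery demonstrates correctness of the inversion and
statistics, not field performance. Real-data headline numbers (e.g.
specific AUCs or the published model's R²/Q²) are not reproducible because
the study data are not deposited; the suite instead checks the machinery's
calibration: ANOVA type-I error within a 3σ binomial band under a
200-feature × 200-replicate null, and stepwise recovery of the planted
3-variable model (Q² > 0.5, planted set selected) in ≥90% of seeded
replicates. The recovery property runs on a 30-subject synthetic cohort:
at n = 11 an 8-variable candidate pool is near-saturated and greedy
selection is unstable — which is itself a faithful reflection of the
original design's fragility, flagged by the package's warning.

Problem sizes in the default test run are deliberately modest (2–4 subject
pipelines for exact recovery, 12–20 feature panels, 15–200 replicate
simulations), chosen as the smallest sizes at which each property is
sharp.

## Known limitations

* No profile-mode centroiding, charge states, or isotope patterns beyond
  the +1 channel; no batch/drift correction beyond IS normalization.
* Blank-in-segment-1 mislabeling (above).
* The Mann–Whitney normal approximation is inaccurate for very small
  groups (exact enumeration is not implemented); the AUC itself is exact.
* The MLR stage models Δ2hPG only; ΔtAUC reuses the same machinery via
  `y=` but ships no dedicated surface.
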