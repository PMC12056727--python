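# Methods

Model, defaults and deliberate deviations. Everything here is a package
design choice; the numbered drivers under `analysis/` and the test suite
exercise these choices on synthetic cohorts with known ground truth.

## Synthetic cohort model

`cohort.generate_cohort` draws, per subject:

- a baseline age uniform on 45–80 and visit ages at 2.4 ± 0.8-year
  intervals (2-decimal precision), with 2–5 WMH, 2–6 PET and 3–7
  cognitive visits;
- true onset ages for V (51.8–78.7) and A (40.8–76.2) with uniform
  marginals joined by a Gaussian copula (`onset_coupling_rho`; 0 = the
  independence null).  A configurable fraction of subjects never becomes
  positive (onset fixed at 150, observations stay on the noise floor);
- observed WMH: exponential growth in raw mL crossing the 2.06 mL
  threshold at onset and doubling every 10 years, floored at 1.0 mL
  pre-onset, with multiplicative log-normal noise (SD 0.12 log-mL).
  `WmhGrowth.a_positive_rate_multiplier` scales the growth rate for truly
  amyloid-positive subjects (1.0 = independence; the configured
  alternative for power checks);
- observed DVR: logistic from 1.0 to 2.5 crossing 1.19 at onset
  (steepness 0.12/y), additive noise SD 0.05;
- cognition: quadratic in (age − 60) with additive A/V slope and
  curvature effects (the A+V+ group declines fastest by construction),
  sex/reading/practice covariates, correlated random intercept and age
  slope, and per-test residual noise; raw test scales are arbitrary
  because the pipeline standardizes internally.

All randomness flows from one seed through per-subject spawned
`SeedSequence` streams: identical configs give bit-identical tables.

## Thresholding

Two-component 1-D Gaussian mixture by EM with deterministic 10th/90th
percentile initialisation, pooled-SD start, tolerance 1e−8, max 1000
iterations; equal- and unequal-variance variants are both fitted and the
BIC winner kept. The positivity cutoff is the intersection of the two
weighted component densities (quadratic in the log-density difference;
closed form when the SDs are equal). Degenerate fits (weight < 1%, SD
collapse, zero-variance data) raise rather than return a cutoff.
Positivity is boundary-inclusive: adjusted WMH ≥ 2.06 mL ⇒ V+,
DVR ≥ 1.19 ⇒ A+, both at the last scan.

## SILA onset estimation

1. Per-subject OLS slope of value on age, placed at the subject's mean
   value (subjects need ≥ 2 scans to train; everyone is estimated).
2. Tri-cube kernel-weighted mean of rate over level on a 200-point grid.
   **Deviation:** the default bandwidth is 10% of the observed value
   range, not 20%. At 20% the never-positive floor mass bleeds into the
   threshold region (measured smoothed rate 0.003 vs true 0.011 DVR/y at
   DVR 1.1), biasing onsets ~5 years early; 10% tracks the curvature
   while keeping support. Smoothed rates are clamped to ≥ 1e−4/y so the
   curve is invertible.
3. Euler integration (step 0.01 y) from (t = 0, value = threshold),
   forward and backward, capped at ±100 years (`t_horizon`): where the
   rate sits on the floor, traversing the remaining range would take
   thousands of years and the resulting times carry no information.
4. The last scan is the reference: its value is inverted on the curve
   (monotone interpolation; values outside the modelled range are clamped
   to the curve ends and flagged), every other scan gets
   `t_ref − (age_ref − age)`, so within-subject spacing is preserved
   exactly; onset age = reference age − reference time.

The analysis pipeline trains the WMH curve on the **log scale**
(accumulation is exponential in raw mL, so the rate-versus-level field is
well-conditioned there); PiB stays raw. On the default cohort (seed 1)
this recovers onsets with MAE 1.62 y / rank correlation 0.950 (V, n=58
truly positive) and 2.00 y / 0.963 (A, n=94). Chronicities are truncated
at −20 only for display-style tables, never for modelling.

## Mixed models and inference

`lmm.fit_lmm` wraps statsmodels MixedLM with a random intercept and
correlated time slope (REML for coefficient inference, ML refit for
information criteria). If the slope variance lands on the boundary and
makes the fixed-effect covariance indefinite, the fit falls back to a
random intercept only and records that on the fit. Inference is
Wald/normal — the original Kenward–Roger degrees of freedom are not
available in this ecosystem; the deviation is recorded in fit metadata.

- **Pruning**: sequential backward elimination respecting marginality —
  only terms not contained in a remaining higher-order term are
  removable; among those with p ≥ 0.05 the highest-order term with the
  largest p goes first. Status main effects, linear time, intercept and
  baseline-age covariates are protected.
- **AICc**: `AIC + 2k(k+1)/(n−k−1)` with k counting fixed effects plus
  variance components, on the ML fit; models within ΔAICc < 2 of the
  minimum are co-best. Model 2 (own chronicity) is excluded from the
  ranking: its time axis is derived from the outcome, so it fits well by
  construction.
- **Simple slopes**: analytic derivative of the fixed-effect mean in the
  time variable, delta-method SEs from the fixed-effect covariance
  (matches finite differences to 1e−6 relative error by test).
- **Robust inference**: joint Wald tests can use a cluster-robust
  sandwich covariance with the CR2 (Bell–McCaffrey) leverage adjustment
  computed on GLS-whitened data. The pipeline uses it for the
  status-by-time interaction blocks in the Aim-2 battery because
  model-based SEs are anti-conservative for the own-chronicity model
  (measured 12–27% null rejection at nominal 5%): the time axis is a
  function of the outcome and the quadratic mean is a working
  approximation. Even the robust test needs enough clusters in this
  heavy-leverage design — measured null rejection 10.8% at 70 subjects,
  8.3% at 120, 5.0% at 160 — so the calibration suite runs its null at
  160 subjects. Coefficient tables and simple slopes keep model-based
  SEs, matching the original analysis style.
- **Aim 3 sensitivity**: the continuous-chronicity model is not nested
  in the categorical-group model, so "AICc and likelihood ratio tests"
  is implemented as an AICc comparison between the two plus LRTs of each
  against the shared base model (age + covariates only).

## Problem sizes in the test suite

Replicate counts are package choices made for the 25-minute suite
budget: independence-null calibration 200 replicates (n=160 subjects) and
power 50 replicates (growth multiplier 4.0, n=100; the effect must be
large because own-chronicity alignment absorbs most of a group
difference — the known low-power property of this model), LRT null
uniformity 200 replicates, coefficient-recovery 60 replicates, pruning
type-I 100 replicates, replication concordance a single seeded pair.

## Limitations

- The generator is a caricature: visitation is missing-completely-at-
  random, growth curves are shared across subjects up to noise, and
  cognitive effects are additive. It is a bench for the machinery, not an
  epidemiological model.
- Onset ages are point estimates; SILA here propagates no uncertainty.
- Robust Wald calibration was verified for the shipped generator and
  design; other designs should re-run `chronicity.calibration`.
- No DICOM/NIfTI handling; inputs are long-format tables.
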