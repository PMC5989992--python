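# Methods

## Model and pipeline

The pipeline relates an `n × p` fingerprint matrix `X` (subjects × fiber
elements, `p ≫ n`, each row scaled to unit sample variance) to a per-subject
response `y`, with intracranial volume (ICV) as the designated confound.

**Decomposition.** Within every training split the thin SVD `X = U S Vᵀ` is
computed on the raw (uncentered) matrix. Leaving the columns uncentered is a
deliberate choice: the shared mean fingerprint then lies inside the span of
the leading principal axes, so a truncated reconstruction recovers it — the
property that justifies treating the component space as a faithful
low-dimensional stand-in for the fingerprint. A `center_columns` flag
switches to conventional centered PCA for comparison. Sign ambiguity is
removed by making each axis's largest-magnitude entry positive; singular
values below `1e-10 × S_max` are truncated as numerical rank.

**Sparse fit.** The response is regressed on `Z = U S` plus ICV under an L1
penalty (squared-error loss for continuous responses, logistic deviance for
binary), glmnet conventions throughout: the objective is scaled by `1/(2n)`,
predictors are standardized to unit SD internally and coefficients
back-transformed (ICV's raw mm³ scale would otherwise nullify its penalty),
and the intercept is unpenalized. All `r` economical components enter the
fit; sparsity, not a variance cutoff, decides which survive.

**Penalty selection.** λ is chosen by inner cross-validation on the training
split only: 10 folds, a 100-value log-spaced path from `λ_max` (the smallest
penalty with all slopes zero, from the KKT bound) down four decades. Two
rules are provided: `min` (deviance minimum) and the conservative `1se`
default (largest λ within one standard error of the minimum). The paper this
machinery follows names cross-validation but not the fold count, path, or
rule; these defaults are the glmnet ecosystem's and are all exposed in
`CVConfig`.

**Confound isolation.** Linear models are *truncated*: the fitted ICV
coefficient (and intercept) are dropped and only the component coefficients
`β*` back-project into the phenotype map `ŵ = V β*`. Predictions
`ŷᵢ = xᵢ·ŵ` carry no intercept — they are scored by correlation, which is
location/scale-invariant, so none is needed. Because the component scores
are mutually orthogonal and ICV is nearly orthogonal to them, including ICV
during the fit barely perturbs the component coefficients, while truncation
guarantees the prediction uses none of it. For logistic models truncation
inside the nonlinear link would distort the probabilities; the confound is
instead handled by reporting an ICV-only benchmark accuracy next to the
full-model accuracy.

**Evaluation.** Fivefold cross-validation with a unique 20% held out per
fold. For binary runs the fold draw is redrawn (up to 100 times) until every
fold's minority-class count is within ±25% of its expectation, with a floor
of one subject (folds hold integer counts; the floor is what makes the
standard 90:10/n=100 case feasible). If every fold's model is intercept-only
the pooled prediction is constant and the correlation metric is flagged
undefined rather than raised. Training metrics are computed from a
full-sample refit (not fold averages) and labeled as model-fit measures.

**Inference.** Permutation tests shuffle `y` (keeping fingerprint–ICV rows
paired) and rerun the entire pipeline per trial; the null statistic is |r|
(continuous) or accuracy (binary). Trials whose null model is intercept-only
are excluded from the p denominator — matching how undefined correlations
must be handled — with a conservative all-trials denominator behind a flag.
If the *observed* statistic is itself undefined, the p-value is NaN: a
constant predictor carries no evidence. Bootstrap CIs resample
prediction–observation pairs (percentile 2.5/97.5); resamples on which the
statistic is undefined are redrawn and counted. FDR control is
Benjamini–Hochberg.

## Synthetic cohorts

The generator draws
`xᵢ = offset + m·μ + Σₖ sᵢₖ σₖ aₖ + εᵢ`,
with `μ` and the latent axes `aₖ` jointly orthonormalized random directions
(scaled so each contributes unit per-element variance), `sᵢₖ ~ N(0,1)`
subject scores, and i.i.d. element noise; rows are then scaled to unit
sample variance. Attributes derive from the latent scores, so each planted
effect has an exactly known fiber-space direction — the truth against which
estimated maps are scored by |cosine|.

Calibration targets the empirical similarity structure of real fingerprint
cohorts. The expected inter-subject Pearson correlation is
`m² / (m² + Σσₖ² + noise²)`; the shared-profile strength `m` is solved from
`target_inter_subject_r` (default 0.42) in closed form. The default latent
scales (five axes at σ = 0.21 against unit element noise) set the spread of
pairwise correlations to roughly ±0.09 (middle 95%), near the tight band
real cohorts show. Repeat scans add fresh element noise at SD 0.2 and
rescale, giving intra-subject correlations near `1/(1+sd²) ≈ 0.96` — above
the 0.90 reliability floor of real repeat scans — while attenuating
inter-subject correlations by under 0.02. Binary attributes threshold a
latent Gaussian at its *empirical* quantile, so class counts are exact,
which is what makes base-rate identities exact rather than approximate. ICV
is lognormal (median 1.5×10⁶ mm³, σ = 0.08, ~8% CV, typical of young-adult
cohorts) and independent of the fingerprints; `icv_loading` mixes the ICV
deviate into the *response only*, never into `X`, so confound-isolation
behavior can be tested cleanly.

What the generator does **not** emulate: spatial autocorrelation between
neighboring fiber elements, non-Gaussian (e.g. strictly positive, skewed)
density distributions (a moderate positive offset is applied, but values can
go negative), registration artifacts, heteroscedastic per-region noise, or
genetic/familial structure between subjects. Passing tests therefore
demonstrate correctness of the *pipeline machinery* under a faithful
covariance/similarity structure, not robustness to every property of real
diffusion data.

## Numerical choices

- **Linear solver.** scikit-learn coordinate descent. Inner-CV path
  evaluation calls the Gram-form CD kernel directly with per-fold Gram
  matrices cached and warm starts along the path; this is exactly
  `lasso_path` (unit-tested equivalence) minus per-call overhead, which
  matters because permutation tests rerun selection thousands of times.
- **Logistic solver.** A proximal-Newton (IRLS) path: at each penalty the
  deviance is majorized by its weighted least-squares expansion and solved
  by coordinate descent, warm-started from the previous penalty, with
  sequential strong-rule screening and KKT checks over excluded
  coordinates. Safeguards: probability weights floored at 1e-5, linear
  predictor clipped at ±30 (quasi-separation), a deviance-plateau stop when
  coefficients drift without improving fit, and a saturation stop
  (mean deviance < 1e-6) that freezes the remainder of the path. Agreement
  with liblinear at high precision is unit-tested.
- **Tolerances.** Path solves used only to *rank* penalties run at
  selection-grade tolerance (1e-3); the refit at the chosen penalty is
  tight (1e-8 CD tolerance, 1e-7 IRLS coefficient-change).
- **Path truncation.** Inner-CV evaluation walks the penalty path in chunks
  and abandons it once an entire trailing chunk sits more than 4 SE above
  the running deviance minimum: penalties past that point can win under
  neither the `min` nor the `1se` rule (whose threshold is min + 1 SE).
- **Degenerate inputs.** Zero-variance predictor columns are excluded from
  fitting and assigned zero coefficients; constant responses, single-class
  labels, constant fingerprint rows, and zero-norm truth directions raise
  informative errors. A probability of exactly 0.5 classifies as class 1
  (a tie-break that must be fixed somewhere for determinism).
- **Seeds.** One top-level seed fans out to fold assignment, per-fold inner
  CV, permutation trials, and the bootstrap via `derive_seed(seed, *tags)`
  (CRC-hashed tags into a `SeedSequence`); every stage is reproducible and
  decorrelated, and all derived seeds stay below 2³¹.

## Experiment sizes used by the test suite

Chosen so the full suite exercises every property at meaningful scale:

- Forced base-rate classification: n = 833 (761/72) and n = 840 (468/372),
  p = 5000, fivefold, `1se` rule — the splits where null labels pin CV
  accuracy to the majority fractions 0.9136 and 0.5571 exactly.
- Permutation calibration: n = 150, p = 1000, 50 repetitions × 200 trials.
  This experiment uses the `min` rule with a reduced inner search (5 folds,
  15 penalties over two decades): under a pure null the conservative `1se`
  rule returns intercept-only fits whose observed statistic is undefined,
  leaving nothing to calibrate, and calibration is a property of the
  permutation scheme that holds for any fixed selection procedure. An
  undefined observed statistic counts as a non-rejection.
- Planted-effect recovery: n = 400, p = 2000, effect explaining 25% of
  response variance, 10 seeds; median map–truth cosine and the pooled CV
  correlation against its √0.25 ceiling.
- Specificity: two attributes on disjoint axes of a 300 × 2000 cohort at an
  SNR where both full-sample maps are nonzero.
- Similarity: 200 × 5000 cohort against the 0.42 ± 0.03 inter-subject and
  0.90 intra-subject targets.

## Known limitations

- The logistic path's loose-tolerance CV scoring can mis-rank penalties
  whose deviances differ by less than ~1e-3; this is far below the
  fold-to-fold noise that selection averages over.
- `pooled_decomposition=True` (one cohort SVD reused across folds) leaks
  held-out rows into the axes; it exists for cheap exploration only and is
  never used by tests or the acceptance script.
- Voxel export uses an identity affine unless the caller supplies geometry;
  the element map records 0-based voxel indices and the LPS sampling order
  as metadata only.
- Per-response complete-case deletion is the only missing-data policy; no
  imputation is offered.
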