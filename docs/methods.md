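# Methods

## The task and the model family

The package models a two-alternative color-categorisation task in which each
trial shows eight colored elements. Hues live on a scale rescaled to
[−0.5, 0.5] with the category boundary at 0 (negative = blue, positive =
red); the observer reports the category of the *average* hue and rates
confidence on a six-point scale. Difficulty is manipulated factorially by
the distance of the mean hue from the boundary and by the spread of the
elements around that mean.

The confidence-extended log-posterior-ratio (c-LPR) family assumes:

1. **Transfer.** Each hue C_i is passed through a transfer function. The
   sigmoidal variants use

       E_i = −1 + 2 / (1 + exp(−C_i / d)) = tanh(C_i / (2d)),

   whose slope parameter d ("compression", hue units) compresses extreme
   hues and amplifies differences near the boundary — the mechanism behind
   robust averaging. The linear variants use E_i = clip(C_i / d, −1, 1);
   with d = 0.5 the full hue range maps exactly onto [−1, 1], and d stays a
   free slope analog of the sigmoidal case.
2. **Noisy averaging.** DV1 = mean(E) + N(0, ε1), with ε1 the decision
   noise ("decnoise", DV units).
3. **Choice.** x = +1 if DV1 > 0, else −1 (the tie at zero goes to −1,
   exactly as the choice rule is written).
4. **Metacognitive degradation.** DV2 = DV1 + N(0, s), with

       s = ε2 · (1 + (var_j − var_1) · γ),

   where ε2 is the metacognitive noise ("metanoise"), γ the unitless
   variance-scaling coefficient ("scalemetanoise"), var_j the element
   spread of the trial's variance condition and var_1 the lowest spread in
   the design. Reading the γ term as the *additional* noise keeps a
   baseline ε2 present at the lowest variance level; the strictly literal
   multiplicative form (which silences metanoise entirely at var_1 and
   makes ε2 unidentifiable in models that estimate it without γ) is
   available behind the `eq4_literal` flag.
5. **Confidence.** DV2 is binned against the fixed criteria
   {+∞, 0.60, 0.35, 0.10, −0.15, −0.40, −∞} for x = +1 (sign-mirrored for
   x = −1) into ratings 1–6. Criteria are never fitted. Bins are
   lower-exclusive/upper-inclusive: DV2 must strictly exceed a criterion to
   move up a bin, matching the strict inequality of the choice rule.

Seven variants differ in which parameters are free (see the table in
`clpr.model`). Variants 4–7 fix ε2 = ε1; variants 3, 5 and 6 use the
linear transfer; variant 7 hard-codes the positive-evidence bias: noise is
added per element (E_i = C_i + N(0, ε1)), the choice still derives from
the compressed mean, but DV2 is the *sum of the raw choice-congruent
elements* plus metanoise, binned against the same criteria. The scale
mismatch between that sum and the criteria is deliberate and left
uncorrected — it is part of why the variant fits poorly. Congruence is
judged on the noisy elements, sign-matched to the realised choice; an
empty congruent set contributes 0. No DV-level noise is added on top of
the element noise in variant 7's choice stage (the choice expression for
that variant carries no noise term).

## Closed-form oracles

For variants 1–6 the pair (DV1, DV2) given a stimulus is bivariate normal
with means mean(E), variances ε1² and ε1² + s², covariance ε1². Choice and
confidence probabilities are therefore exact orthant/strip probabilities;
`clpr.oracles` evaluates them with a vectorised Owen's-T bivariate normal
CDF. Degenerate cases are handled explicitly: ε1 = 0 makes DV1
deterministic (univariate binning of DV2); s = 0 collapses DV2 to DV1
(univariate binning of DV1); |ρ| → 1 falls back to the Fréchet limits.
The implementation is tested against scipy's quadrature-based bivariate
normal CDF and against Monte-Carlo frequencies from the trial simulator;
scipy's own CDF is point-wise and far too slow to sit inside an
optimisation loop, which is why the Owen's-T route exists.

## Fitting and model comparison

Models are fitted per agent to the cell-level summary surface: the mean
accuracy and mean confidence of each (mean level × variance level) cell,
pooling the two (symmetric) categories. The cost is

    SSE = Σ_cells (oACC − pACC)² + Σ_cells (oCJ − pCJ)²,

confidence on its raw 1–6 scale (a `normalize_confidence` option maps it
to [0, 1] for users worried about scale imbalance). Predicted cell means
come from the deterministic oracle for variants 1–6 — making the
objective smooth, noise-free and exactly reproducible — and from
fixed-seed Monte-Carlo simulation (default 2000 responses per cell) for
variant 7. An optional `max_pred_stimuli` cap (a deterministic head
subsample per cell, 250 by default in the batch harnesses) bounds the
oracle's per-evaluation cost on very large datasets; the residual
ensemble error it introduces is far below the sampling noise of the
observed cell means at those sizes.

Optimisation uses `scipy.optimize.differential_evolution` with bounds
compression (1e−5, 0.2), decnoise (1e−5, 0.3), metanoise (1e−5, 0.3),
scalemetanoise (0, 10), population multiplier 8, `tol=1e-8` and a final
local polish. The reference procedure ran 1000 generations; with the
smooth analytic objective and the polish step the optimum is reached in a
few dozen generations, so the harnesses default to budgets of 10–25
generations (`budget` is always exposed). Fits are bit-reproducible given
a seed.

Model comparison uses AIC = 2k + n·ln(SSE/n) with k the number of free
parameters and n = 2 × (number of cells) — one accuracy and one
confidence point per cell, matching the two SSE sums. SSE = 0 (possible
only for degenerate noiseless data) is reported as −∞ rather than fed to
the logarithm. The winner is the lowest mean AIC across agents; ties go
to fewer free parameters.

## Hue-rank regressions and contrasts

For the reverse-correlation analyses each trial's hues are sorted
ascending (rank 1 = bluest); choice is regressed on the eight ranked hues
with a logistic link and confidence with a linear link, split by stimulus
category (or by response), with an intercept and unstandardised
predictors. Fits are ordinary fixed-effects regressions: the synthetic
data are homogeneous single-population agents, so the nested
random-effects machinery used with multi-experiment human data would
estimate nothing.

Contrast conventions (the signs of raw weights are arbitrary, so they are
fixed explicitly):

* The **slope** contrast is w·β with centered unit-spaced weights
  (−3.5 … +3.5). For confidence fits the betas are first *oriented* by
  the category sign (β̃ = category · β), because the direction of the hue
  effect on confidence inverts between categories. Under robust
  averaging this yields a negative slope for red and a positive slope for
  blue — opposite signs for the two categories — while a color mirror of
  the data flips each slope's sign.
* The **congruency** contrast is mean(β̃ over incongruent ranks) −
  mean(β̃ over congruent ranks), incongruent being ranks 1–4 for red and
  5–8 for blue. Positive values mean confidence leans on incongruent
  evidence (the RIE pattern) for *both* categories.
* The **inlying/outlying** contrast, used for choice fits, is
  mean(β over ranks 3–6) − mean(β over ranks 1, 2, 7, 8) on raw betas.

Standard errors come from the fit's coefficient covariance (Wald z for
logistic, t for linear). Perfect separation in a logistic fit is flagged
and the coefficients are returned with a warning rather than discarded.
The drop-one analysis refits the confidence regression eight times, each
time omitting one rank, and reports R² and its drop from the full model.

## Synthetic data: what it emulates and what it does not

`clpr.stimuli` draws the eight hues i.i.d. normal around category ×
mean-distance, re-centers them so the sample mean is exact (the task used
tightly controlled stimulus sets; a switch disables this), and clips to
[−0.5, 0.5]. Clipping after re-centering can bias extreme cells slightly;
this is documented rather than corrected. Re-centering shrinks the
per-element SD by √(7/8) relative to the nominal spread — visible in the
element-level tail checks but irrelevant to any fitted quantity, since the
same stimuli enter observation and prediction. Category labels follow the
generative mean's sign. Default levels are mean ∈ {0.03, 0.06} and spread
∈ {0.05, 0.15} hue units: the exact empirical levels are not published,
and these put simulated accuracy in the high-70s-to-low-90s band typical
of the task. One seeded generator drives each dataset; all batch
harnesses derive per-agent substreams deterministically.

The generator emulates the stimulus statistics and factorial structure of
the task, not its psychophysics: no lapses, no response bias, no
confidence-scale idiosyncrasies, no learning or session effects, and a
single homogeneous "participant" distribution. Passing tests therefore
demonstrate the internal consistency and recoverability of the model
machinery on data that obey it — not that human data do.

## Validation harnesses

* **Parameter recovery** draws compression ~ U(0.00001, 0.2) and decnoise
  ~ U(0.00001, 0.3) per agent, simulates the winning variant on the 2×2
  design (trials split equally across the eight category × mean × variance
  cells; 250 trials per agent means 31 per cell), refits, and reports
  Pearson and Spearman correlations. `scripts/acceptance.py` runs 40
  agents at 8000 trials and 60 at 250 trials with a budget of 15
  generations — sizes chosen so both regimes finish in a few minutes on
  one CPU while leaving the correlations stable to the second decimal.
* **Model recovery** generates datasets under each candidate variant
  (parameters drawn from the fitting bounds), cross-fits all candidates,
  and tabulates how often the generating variant wins on AIC.
* **The medium-condition dissociation** is evaluated on oracle
  expectations: a high-mean/high-variance cell is calibrated by root
  finding to match a low-mean/low-variance cell's expected accuracy
  exactly; only variants with γ > 0 then predict lower confidence in the
  high-variance cell, while the γ-free winning variant predicts neither
  difference. The frozen test configuration (d = 0.12, ε1 = 0.25,
  μ_low = 0.05, spreads 0.05/0.15, γ = 6) was chosen so the γ-free model
  is genuinely neutral on confidence (|Δ| < 0.01 on the 6-point scale) —
  at strong compression settings even accuracy-matched cells differ in
  expected confidence through the shape of the DV distribution alone,
  which would confound the comparison.
* **The context experiment** builds one purple stimulus set (mean hue 0)
  plus blue/red flanker sets at ∓offset, simulates responses with hues
  expressed relative to each context's boundary at ∓offset/2, and tests
  whether the purple-trial confidence slope (oriented by the
  boundary-relative category) is negative in the Blue Context and
  positive in the Red Context. Physical purple hues are bit-identical
  across contexts; the physical hues are clipped half an offset inside the
  scale limits so both boundary shifts stay representable. The default
  300 trials per context mirrors the reference study's single-participant
  session; the reproducibility tests use larger per-context counts,
  i.e. pooled-population scale, since a lone 150-purple-trial session is
  dominated by regression noise.

## Numerical and degenerate-input choices

* Choice ties (DV1 = 0) go to −1; confidence ties sit in the lower bin.
* `shift_boundary` re-expresses hues exactly (no re-clipping) and rejects
  shifts that leave the representable range, so round-trips restore hues
  to within one ulp.
* AIC at SSE = 0 raises with guidance to use the −∞ sentinel (the batch
  fitters do this automatically).
* Single-cell designs fit with a warning; empty design cells are an error
  naming the cell.
* Hue-rank sorting is stable for ties.

## Known limitations

* Because the fit surface is the handful of cell means prescribed by the
  cost function, the sparsest regime (250 trials ≈ 31 per cell) only
  partially identifies decision noise: compression recovers with r well
  above 0.95, but decnoise recovery plateaus near r ≈ 0.9 regardless of
  optimiser budget — a delta-method estimate puts the per-agent decnoise
  standard error near 0.05 against a 0.087 SD of the generative draws,
  and strong-compression agents saturate accuracy, flattening the SSE
  surface in decnoise. Trial-level likelihood fitting would identify it
  better but is a different estimator than the cell-mean SSE implemented
  here.

* Variant 7's objective is Monte-Carlo (fixed-seed) and therefore noisy in
  parameter space; its fitted optima are less precise than the analytic
  variants'.
* The empirical AIC table and human-data regression magnitudes depend on
  the original datasets and are out of scope; contrasts on simulated data
  are interpreted by sign and relative magnitude only.
* Dynamic (sequential-sampling) confidence models and fitted confidence
  criteria are out of scope.
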