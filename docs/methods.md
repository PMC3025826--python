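# Methods

`prognomod` implements a combined clinical + genomic prognostic-modelling
workflow for breast-cancer expression cohorts: gene-module scoring, batch
integration, sparse penalized survival and response models, and resampling
validation. This note records the models, the conventions where several
defensible choices existed, and what the synthetic cohorts do and do not
emulate.

## Gene-expression modules

A *module* is a named gene set treated as a single per-sample variable.
Four scoring routes are supported, matching the ways signatures are
constructed in the literature:

- **median** — each member gene is centered by its median across a
  reference sample set, and the score is the per-sample median of the
  centered values. Median centering makes the score location-free across
  platforms; it can be disabled by passing a zero reference.
- **first_pc** — member genes are z-scored (reference mean/SD) and the
  score is each sample's projection on the first principal axis of the
  reference submatrix. The axis sign is chosen so the score correlates
  non-negatively with the mean member-gene profile (a `direction_hint` of
  ±1 overrides this); the score is centered and scaled to unit reference
  variance. Zero-variance genes are dropped with a warning.
- **centroid_corr** — the correlation between a sample's member-gene
  profile and each supplied class centroid, one output row per centroid
  (`module.centroid`). Spearman rank correlation is the default, as in the
  nearest-centroid subtype literature; Pearson is available. Constant
  profiles yield a missing score (the correlation is undefined).
- **published_model** — a frozen linear model, offset plus per-gene
  weights; genes absent from the matrix contribute zero and are reported.

Gene matching is case-insensitive on symbols. A module is scoreable when at
least `min_fraction` (default 0.5) of its genes are present; signatures
routinely lose genes when cohorts are merged across platforms, and 0.5 is a
permissive but non-trivial floor. Unscoreable modules are dropped from the
score matrix and flagged in the match report rather than failing the run.

All scoring constants (medians, z-score parameters, principal axes) can be
derived from a *reference* subset — the training samples — and applied to
held-out samples, so resampling protocols are leakage-free. `run_round`
re-derives constants on each training split when given the expression
matrix and registry (`rederive=True`); by default it consumes a precomputed
global score matrix, which is cheaper and matches common practice when the
score matrix is treated as a fixed feature table.

## Batch integration

Multi-platform cohorts carry per-batch location shifts. `dwd_adjust`
implements Distance Weighted Discrimination batch correction: for each
batch against the largest (reference) batch it fits the DWD separating
direction — minimising the sum of reciprocal margins, with the standard
linearised tail below margin `1/sqrt(C)` and `C = 100 / median
inter-batch distance²` — and translates the batch along that direction
until the two batch means coincide on it. The optimisation runs in the span
of the centered samples (via SVD), so cost scales with sample count rather
than gene count, and is solved with L-BFGS using an analytic gradient.

The fit-and-translate step repeats (default at most 5 times) and stops when
the mean gap along a freshly fitted direction falls below a threshold. The
default threshold is adaptive — twice the standard error of the mean
projection difference — so the procedure removes systematic shifts but does
not chase sampling noise; because the stopping check precedes any
translation, re-running the adjustment on already-adjusted data is an exact
no-op. A per-gene per-batch mean-centering fallback (`mode="mean_center"`)
is provided for batches too small (< 3 samples) to fit a direction.

## Cohort assembly rules

- **Complete-case filter** drops samples missing any required clinical or
  outcome field and logs the retention percentage.
- **Follow-up cut-point** (default 7 years) applies administrative
  censoring: records beyond the cut-point become (time = cut-point,
  event = 0).
- **HER2 surrogate**: when clinical HER2 is unavailable, status is derived
  from HER2 (ERBB2) mRNA with the top 20% of expressers called positive —
  exactly `ceil(0.2 n)` samples, ties at the boundary broken by ascending
  sample id (deterministic, with a warning). The threshold is applied to
  the combined cohort by the caller; nothing prevents applying it
  per-source instead.
- **Subtype assignment** is nearest-centroid by correlation (same flavour
  as centroid modules); exact ties go to the lexicographically first
  centroid with a warning. Centroid sets are user-supplied inputs; the
  package bundles none.
- **Subgroups** (all, ER±, HER2+, ER+/HER2−, Luminal = LumA ∪ LumB,
  Basal-like, HER2-enriched) are deterministic predicates over the clinical
  and subtype columns.

## Penalized risk models

`LassoCox` maximises the L1-penalized Cox partial likelihood (Breslow
ties) along a descending lambda grid — 50 points from just above the
analytic lambda_max (the largest score-equation gradient at beta = 0,
divided by n) down to 1% of it. The coordinate-descent path is computed by
scikit-survival's Coxnet; grid points at or above lambda_max are exactly
zero by construction. Lambda is chosen by seeded k-fold (default 10)
cross-validated partial-likelihood deviance in the Verweij–van Houwelingen
form, minimum rule by default with the 1-SE rule behind a flag. Folds are
stratified by event status so each fold retains events. Design matrices are
standardized internally; training means/SDs travel with the results object
so test samples are always encoded with training constants.

Clinical variables enter as ER/HER2 binary, tumor size binary
(< 2 cm vs ≥ 2 cm) and grade ordinal 1–3; module scores enter as-is and are
standardized with everything else (default on, like any other column).

The **risk score** is the linear predictor centered at the training means —
the log hazard ratio relative to the training-average patient — so the
conventional high/low threshold of zero is meaningful on held-out data.
Scores exactly at the threshold are labelled low risk (a measure-zero case;
the rule is fixed for reproducibility).

`LassoLogit` is the binary-response analogue: L1-penalized logistic
regression (scikit-learn saga solver, intercept unpenalized grid-wise via
the analytic lambda_max shortcut), lambda by seeded CV on held-out
deviance. At full penalty the model predicts the training prevalence.

## Evaluation

- Kaplan–Meier product-limit curves with Greenwood standard errors; events
  are processed before censorings at tied times.
- k-group log-rank chi-square with df = k − 1.
- Univariate Cox on the continuous risk score; the reported p-value is the
  Wald test by default (likelihood-ratio behind a flag). Monotone
  likelihood (a perfectly separating score) is flagged, not fatal.
- **Harrell's C**: comparable pairs are (i, j) with t_i < t_j and
  event_i = 1; concordant when the earlier failure has the higher score;
  tied scores count 1/2. Implemented in-package because library
  implementations differ in tied-time handling; the suite checks it against
  exhaustive pair enumeration.
- Rank-based (Mann–Whitney) ROC AUC with tie correction.
- **Success rule**: a model counts as prognostic only if it is non-empty
  and its Cox p-value is below 0.05 on both the training and the testing
  set.

## Resampling designs

`stratified_split` partitions each cross-classified stratum after a seeded
shuffle, allocating floor or ceil of `ratio × cell size` to training —
whichever keeps the running global count closest to target — so every cell
is within one sample of the target fraction and the global split is exact
(e.g. 225 → 150/75 at ratio 2/3). Singleton cells go to training.

`run_resampling` repeats split → fit → evaluate with derived seeds
(base + round index, so any round is reproducible in isolation) until the
target number of successful models (cap `max_attempts`); selection counts
are tabulated over successful rounds only, with the direction of
association (positive coefficient = poor prognosis). Mean test C-index per
family uses every evaluated round; the superiority matrix counts strict
inequalities, leaving ties out of both cells. Both attempted and successful
counts are reported, since "N successful rounds" and "N rounds" are
different protocols.

`run_pcr_experiment` mirrors the design for a binary response: split
stratified by response, ER and HER2 (redrawn with the next seed if a side
is single-class, bounded retries), one `LassoLogit` per family, train/test
AUC, and the selected variables with their response direction.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
microarray physics. Member genes of module m are
`sqrt(rho)·Z_m + sqrt(1−rho)·noise` for a latent standard-normal module
score `Z_m`, giving average within-module pairwise correlation rho
(default 0.7); non-module genes are independent noise. Batches add
per-(batch, gene) N(0, `batch_shift_sd`) location shifts. Clinical
categories are thresholded latent Gaussians correlated with designated
module scores, which reproduces ER/module confounding without extra
machinery; prevalences default to the combined-cohort values (ER+ 71.8%,
size < 2 cm 56.2%, grade 17.8/33.1/49.1%, HER2+ 20%).

Relapse times are exponential with hazard `lambda_0 · exp(eta)` on
standardized covariates (defaults: `lambda_0` = 0.05 events/year, two
prognostic modules at ±0.6–0.8 plus grade/size — chosen as realistic
standardized log-hazard effects, since the source analyses do not report
effect sizes); censoring is independent exponential at 0.10/year, and the
7-year administrative cut-point is applied downstream. Binary response is
Bernoulli(logistic(intercept + eta)) with intercept −1.1 (≈ 25%
prevalence, typical of pCR). Exponential baseline and censoring keep
closed-form sanity checks (median = ln 2 / rate); a Weibull hook is left
open. A fixed seed reproduces every matrix and table byte-for-byte, and the
saved truth file regenerates the cohort exactly.

What the generator does **not** emulate: probe-level artifacts,
normalization pipelines, realistic gene–gene networks beyond block
correlation, non-proportional hazards, or informative censoring. Passing
tests therefore demonstrate that the machinery recovers planted structure
under its own assumptions, not that it would perform identically on real
cohorts.

## Problem sizes used by the test suite

The heavier suites run at sizes chosen to make their statistical assertions
stable: planted-signal recovery uses 300 samples, 100 candidate modules (5
prognostic) and 50 resampling rounds; null error control uses 100 rounds
over 30 modules; permutation-null uniformity uses 300–400 replicates.
Parameter-recovery checks of the generator refit unpenalized models on
cohorts of 2 000–5 000 samples across 50 replicates.

## Known limitations

- DWD adjustment removes a single location direction per batch pair;
  scale or covariance batch effects pass through.
- The lambda grid floor (1% of lambda_max) can truncate very dense
  solutions when p is far below n; pass explicit `alphas` for those cases.
- The Cox CV deviance uses Breslow tie handling throughout, which is
  slightly anticonservative under heavy ties.
- Centroid modules require user-supplied centroid values; published
  centroid sets are inputs, never bundled.
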