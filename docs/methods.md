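# Methods

## The estimator

Physiological age is defined operationally: it is the mean age a panel of
models assigns an individual when that individual is held out of training.
One ensemble iteration comprises

1. age binning — half-open equal-width bins (default 5 y) anchored at a
   multiple of the width; empty bins are dropped; a bin's label is its
   center age. Five-year bins give ~17 classes over a 15–100 y cohort,
   enough classes for a meaningful discriminant projection while keeping
   per-class counts usable;
2. a stratified 90/10 split drawn independently within every bin (at
   least one test member whenever a bin has ≥ 2; a singleton bin is always
   trained on and flagged);
3. Fisher scoring of every trait on the *training rows only*:
   F_j = Σ_k n_k(μ_jk−μ_j)² / Σ_k n_k σ²_jk with class-size weights and
   population variances; a zero denominator scores 0; ties keep input
   order. The score is recomputed per split (the global trait count k is
   fixed, the identity of the top-k traits may vary);
4. optionally, projection of the k kept traits onto N−1 linear
   discriminants fitted on the training rows (scikit-learn
   `LinearDiscriminantAnalysis`, svd solver — chosen over a hand-rolled
   eigensolver because the svd path handles singular within-class scatter
   without an explicit ridge and is the implementation practitioners use);
5. an age model fitted on the training rows. The reference family is a
   random-forest classifier (30 trees, Gini, min split 2, min leaf 1)
   over bin labels, decoded to bin-center ages; linear, lasso,
   elastic-net, kNN and SVR regressors are available for cross-model
   agreement checks. A split whose training side lost an entire bin is
   skipped and counted.

Per-individual predictions are aggregated over that individual's test
appearances only: the mean is the physiological age, and the spread is
reported as a *population* SD (an explicit convention, since with ~M/10
appearances the two SD conventions differ visibly). Individuals with zero
appearances are excluded and logged. M defaults to 10,000; means stabilize
far earlier (the SD of the mean shrinks as 1/√appearances), so analyses
and tests in this repository use M = 150–500 and state so.

Reproducibility: a master seed spawns one child seed per iteration
(`numpy` `SeedSequence`), so results do not depend on execution order.

### Recalibration

Regression-to-the-mean compresses predictions toward the cohort center,
making PAR systematically > 1 for the young and < 1 for the old. The
correction fits pred = a + b·age by least squares and outputs
(pred − a)/b — the inverse of the calibration line, the simplest member of
the linear-rescaling family; a trimming mode that drops the youngest and
oldest bins is also provided, because edge bins are where one-sided
shrinkage is worst. Rescaling requires b > 0 and errors otherwise.

### PAR and rate ratios

PAR = physiological age / chronological age, exactly; "expected" is
reserved for |PAR − 1| ≤ 1e-9, otherwise the label is slower/faster. The
same arithmetic is exposed as a generic `rate_ratio` for externally
supplied clock ages (e.g. a DNA-methylation age), whose agreement with PAR
is quantified by Pearson r/R² and by the partial correlation after
least-squares residualization of both vectors on an intercept, age and
sex (the estimator behind "adjusting for age and sex"; any other choice of
partialling would need its own justification, and this is the standard
one). Regressor families can emit non-positive predicted ages at the
young edge before recalibration; such individuals are dropped from PAR
tables with a logged count rather than given an undefined rate.

## Mortality association

**Cox model.** Survival time is years from baseline to death, censored at
the end of the follow-up window; covariates are baseline age (years), sex
(0/1), and log2(PAR), so a coefficient β reads as an exp(β)-fold hazard
per doubling of the aging rate and exp(β·log2 q) per q-fold change. The
fit delegates to lifelines (`CoxPHFitter`, Efron ties, Newton–Raphson) —
a standard model fit, not this package's contribution; tests pin the
implementation against a brute-force partial-likelihood maximization on
tie-free toys. Zero-variance covariates are dropped and reported, not
estimated.

**Age-matched randomization test.** Per repetition, every deceased
participant draws one living partner uniformly from those within ±0.5 y
of their age — without replacement within the repetition when possible,
falling back to with-replacement (logged) when a window is exhausted —
and the paired differences ΔPAR feed a one-sided one-sample t-test of
mean ΔPAR > 0. The p-value at t = 0 (including the all-zero degenerate
case) is defined as 0.5. Deceased with no living partner in the window
are excluded once and logged. Default 10,000 repetitions.

**Randomized control.** Before every repetition the deceased/living
labels are permuted uniformly at random, preserving counts, then one
matched comparison runs. Re-randomizing each repetition makes repetitions
near-independent, so the long-run significant fraction is the nominal
level (~5%), the positive-ΔPAR fraction ~50%, and the grand mean ΔPAR ~0
— the quantities the acceptance script recomputes.

## The synthetic cohort

The generator encodes the structure the estimator assumes, so parameter
recovery is a meaningful test:

- latent rate ρ = exp(N(0, σ)), σ = 0.08 by default — chosen so the PAR
  spread matches an observed distribution with mean ≈ 1.04 and median
  ≈ 1.00; true physiological age P = ρ·age; ages uniform on 15–100 y;
- traits (default 100 continuous + 30 ordinal + 10 binary = 140, cohort
  n = 4,000): x = α_j + β_j·z(g_j(P)) + γ_j·sex + ε with link g_j cycling
  through identity / log / saturating (P/(P+50)), z standardized on the
  baseline population, β_j = ±0.6 (random sign), sex offsets N(0, 0.2),
  ε ~ N(0, 1). Ordinal traits threshold a latent trait at population
  quantiles into 3–5 levels; binary traits are Bernoulli of a logistic
  transform. Missingness, when enabled, is completely at random;
- mortality hazard λ·e^(θ·age)·ρ^γ with λ = 2.6e-5 /y, θ = 0.09 /y,
  γ = 2, follow-up 2.5 y. Two choices matter here. First, the latent
  rates are sampled *conditional on survival from birth to the baseline
  age* (importance resampling against the from-birth survival
  probability): old enrollees of a real cohort are depleted of fast
  agers, and without this survivor bias the lifespans of the deceased
  would be essentially uncorrelated with ρ, which would make the
  lifespan–rate correlation untestable. Second, the age at death is drawn
  from the window-truncated conditional death-time distribution (inverse
  CDF of the ρ-scaled Gompertz) rather than an arbitrary positive offset,
  keeping death timing hazard-consistent. λ and θ are human-scale
  from-birth Gompertz values, and the follow-up window is then calibrated
  so a 4,000-person cohort yields ~260 in-window deaths — the scale at
  which the downstream tests are meant to operate. A consequence of
  combining a human-scale from-birth hazard with enrollee ages up to
  100 y is a short window and hence ~10,000 person-years, well below what
  a decade-long study would accumulate; analyses that care about absolute
  person-years should lengthen `follow_up` and accept the higher death
  count;
- follow-up waves advance age by `wave_gap`, keep ρ fixed up to an
  optional drift, regenerate traits from the updated P with the *frozen*
  baseline trait model (same coefficients, standardization and ordinal
  cuts), and omit individuals whose death time precedes the wave.

What the simulator does **not** emulate: realistic trait covariance
(traits are conditionally independent given P and sex), family structure,
genotypes, informative missingness, measurement batch effects, and
age-dependent trait variances. Passing tests therefore demonstrate that
the pipeline recovers rates under its own structural assumptions — not
that it would perform identically on real cohort data.

## Trait ranking

- *Quartile volcano*: lowest vs highest PAR quartile (boundary ties by id
  order), Welch two-tailed t per trait — Welch rather than pooled
  variance because equal variances across extreme quartiles is exactly
  the kind of assumption a volcano should not make (a pooled-variance
  switch exists); fold change = ratio of quartile means, with a flagged
  mean-difference fallback when a quartile mean is non-positive (ratios
  are meaningless for signed traits); Bonferroni threshold α/T with T
  taken from the data, never hard-coded. A trait constant in both
  quartiles gets p = NaN and ranks last.
- *Correlation ranking*: per-trait Pearson r with physiological age,
  ranked by |r|, sign retained; constant traits rank last.
- *Added value*: ΔR²(t) = R²(baseline) − R²(without t), with Fisher
  selection re-run on the reduced trait set over the *same* split plans
  as the baseline (paired comparison removes split noise); negative
  values are reported, not clipped. Default 500 splits per trait;
  analyses here use 15–50 and say so.
- *Concordance*: Spearman ρ over the shared traits of two rankings.

## Numerical conventions and degenerate inputs

- Missing-data cleaning alternates threshold-based drops (default: keep
  traits/individuals that are ≥ 80% complete) and, once thresholds no
  longer bite, greedily drops the worst-offending trait or individual
  (traits first on ties) until complete-case — deterministic, monotone,
  idempotent. Emptying the matrix is an error that reports the
  thresholds.
- Missing tokens: empty string, NA, NaN (case-insensitive). CSV vs TSV by
  file extension; floats written with 17 significant digits so round-trips
  are exact.
- Trait kinds: ≤ 2 distinct values → binary; ≤ 10 distinct integer-coded
  → ordinal; else continuous; a descriptor file always wins.
- Ordinal and binary traits enter Fisher scoring and LDA as their numeric
  codes; the forest consumes them natively.
- Fisher scores, bin assignment, and the split engine are invariant to
  permuting individuals; regressor predictions are invariant to trait
  column order.

## Problem sizes used in this repository

Tests and analyses run at reduced depth chosen for stability-per-compute:
cohorts of 500–4,000, M = 60–500 splits, 2,000 matched-test repetitions.
The acceptance script estimates PARs with M = 150 (≈ 15 test appearances
per individual) and runs 20,000 control repetitions, giving Monte-Carlo
standard errors of ~0.2 percentage points on the reported fractions.

## Known limitations

- The estimated-PAR mortality signal is attenuated relative to the latent
  rates (estimation noise adds to ρ): a single simulated replicate can
  leave the Cox log2(PAR) coefficient borderline even though the matched
  test shows ΔPAR > 0 almost always. Deeper ensembles (larger M, more
  informative traits) close the gap.
- `select_k` optimizes mean test R² over a candidate grid; it does not
  penalize model size, so flat curves resolve to the smallest tied k by
  convention.
- The classifier family cannot predict outside the bin-center range by
  construction; its predictions are discrete before averaging.
- Cox fitting assumes proportional hazards and uses baseline age as a
  fixed covariate; no time-varying covariates or competing risks.
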