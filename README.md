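# physioage

Estimation of **physiological age** and the **physiological aging rate
(PAR)** from mixed-type quantitative traits, with the downstream
mortality-association tests and trait rankings that make the rate useful,
and a synthetic-cohort simulator with known latent aging rates so the whole
pipeline can be exercised and validated without access to any private
cohort data.

Intended users: biostatisticians and epidemiologists studying biological
aging in cohort data — anyone who has a table of individuals × clinical
traits plus chronological ages and wants a per-individual aging rate that
can be tested against survival.

## The method

Individuals are binned by chronological age (default 5-year, half-open
bins). For each of *M* iterations the cohort is split 90/10 within every
bin; traits are ranked on the training rows by a class-size-weighted
Fisher score

F_j = Σ_k n_k (μ_jk − μ_j)² / Σ_k n_k σ²_jk

over age bins *k*, the top *k* traits are projected onto N−1 linear
discriminants, and a model (reference family: random-forest classifier
with 30 trees, Gini impurity, min split 2, min leaf 1, trained on bin
labels and decoded to bin-center ages) predicts age for the held-out 10%.
An individual's **physiological age** is the mean of their test-set
predictions across all splits, recalibrated against the identity line,
and their aging rate is

PAR = physiological age / chronological age,

so PAR > 1 means aging faster than chronological-age peers and PAR < 1
slower. Downstream, the package provides

- a Cox proportional-hazards fit of survival on log2(PAR) with age and sex
  as covariates (a coefficient β means an exp(β·log2 q)-fold hazard per
  q-fold PAR change);
- a randomized age-matched mortality test: each deceased participant is
  paired with a living participant within ±0.5 y of age, ΔPAR =
  PAR_deceased − PAR_living is tested one-sided for mean > 0, and the
  pairing is repeated thousands of times, with a label-permutation control
  that calibrates the procedure's null behavior;
- trait rankings by PAR-quartile Welch-t volcano (with Bonferroni
  threshold α/T), correlation with physiological age, and
  leave-one-trait-out ΔR².

The simulator draws a latent rate ρ per individual (log-normal, σ = 0.08),
builds traits as noisy monotone functions of ρ·age, and gives mortality a
hazard λ·e^(θ·age)·ρ^γ with survivor-bias-consistent sampling, so recovery
of ρ by the pipeline is a meaningful end-to-end test.

## Worked example

```
physioage simulate --n 4000 --seed 20260929 --out results/cohort
python analysis/02_estimate_physio_age.py
python analysis/03_mortality_tests.py
```

prints (numbers from an actual run; the ensemble here uses M = 300 splits):

```
PAR vs true latent rate: r = 0.621
physiological age vs chronological age: R^2 = 0.931, MAE = 5.06 y (n = 4000)
PAR: mean 0.997, median 0.992; corr(PAR, age) = 0.062 after recalibration

Cox: 266 deaths, 9653 person-years
  log2(PAR): coef 0.87 -> a two-fold higher aging rate multiplies the hazard by 2.38 (p = 0.0744)
age-matched test: 33.5% of 2000 reps significant (p<0.05), mean dPAR 0.0103, 98.6% positive
randomized control: 4.4% significant, mean dPAR -0.0002, 50.0% positive
lifespan vs PAR among 266 deceased: r = -0.255
```

Reading this: the ensemble explains 93% of chronological-age variance and
its PAR estimates correlate 0.62 with the true latent rates; the estimated
rates carry a real mortality signal (nearly every age-matched comparison
has ΔPAR > 0, and the deceased's lifespans correlate negatively with
their PARs), while the label-permutation control sits at its nominal ~5% /
~50% / ~0 null behavior. A single simulated replicate at this depth leaves
the Cox coefficient borderline (p ≈ 0.07); with the noiseless latent rates
it is strongly significant, so the attenuation is estimation noise, not a
missing signal.

The numbered scripts under `analysis/` run the full narrative
(simulate → estimate → mortality → rank) and write their tables under
`results/`. The same stages are available as a CLI
(`physioage simulate|clean|fit|par|mortality|rank|run-all`) driven by one
YAML config with dotted-key overrides.

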