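# Methods

## Synthetic cohort model

The generator is a hierarchical sampler designed to emulate the marginal
structure of a complete-case acute-SCI trial cohort, not any individual
patient trajectory:

- **AIS grade** ~ categorical; cohort default 65.2/10.8/19.8/4.2% (A/B/C/D).
- **Sex** ~ Bernoulli(p_male = 0.793), **NLI** ~ Bernoulli(p_cervical = 0.744),
  sampled independently of severity.
- **Age** ~ normal truncated to [16, 80] years. The parent parameters
  (25.5, 14.8) were solved analytically so that the *truncated* mean is
  32.0; the truncated SD is ≈ 10.7, somewhat below the published 13.3 —
  with a hard floor at 16 and mean 32, a truncated normal cannot reach an
  SD of 13.3 (real age distributions are right-skewed).
- **Week-0 LEMS**: 0 with a grade-specific zero-inflation probability
  (A: 0.97 … D: 0.08), otherwise a rounded gamma clipped to [0, 50].
- **Recovery gain** (week 0 → 26): zero with probability 1 − p_gain
  (grade-ordered: severe injuries often do not recover), otherwise gamma
  with grade-specific mean (A: 12 … C: 30); 75% of the gain is realized by
  week 16.
- **Week 52** = week 26 + round(N(1.5, 2.0)), clipped to [0, 50]; patients
  with a week-26 score of 0 stay at 0. This produces the documented
  plateau (population mean increase ≈ 0.6–0.7 points) while keeping the
  zero-inflated mode intact.
- **Week-26 scores** are additionally masked MCAR at 5%, mirroring the
  ~5% natural gaps in complete-case trial data, so LOCF's donor-missing
  branch is exercised.

Per-grade parameters were calibrated once against the published cohort
moments (targets within ±30%): at n = 10⁵ the generator yields week-0
LEMS mean 2.1/SD 6.8 (target 2.7/7.1), week-26 10.8/15.7 (11.9/18.9),
week-52 11.4/16.1 (12.6/19.3), all medians 0, male fraction 0.792,
cervical 0.746, age mean 32.0. These are calibration defaults shipped in
`scimiss/data/default_generator.yaml` (versioned), not ground truth.

**What the generator does not emulate:** correlations of sex, age and NLI
with severity or with each other; within-patient trajectory shapes beyond
the three-point gain/plateau skeleton; upper-extremity or sensory scores;
grade conversion over time. Consequently, tests passing on synthetic data
show the pipeline's mechanics and the direction of imputation effects, not
real-data effect sizes. One concrete consequence: Little's-test power
under MAR-on-sex derives solely from the sex-mean shift between
missingness patterns, whereas in real data sex–severity correlations add
power.

## Bootstrap subsets

Target per-grade counts are `round(n·p_g)` with largest-remainder
correction (deterministic, lowest-label tie-break) so they sum exactly to
n; sampling is with replacement within each grade stratum, making the
realized composition exact by construction. The subset composition
constant `EMPIRICAL_GRADES` is 65/11/20/4%, which at n = 500 gives
325/55/100/20; the balanced design gives 125 per grade.

## Amputation

All mechanisms blank exactly k = round(rate·n) entries of one variable
(default rate 0.30 → k = 150 at n = 500). "r times more likely" is
interpreted as a ratio of per-entry missingness *probabilities* (not
odds); at these rates the two differ little. The base probability solves
`r·n_high·p + n_low·p = k`; per-group integer counts come from
largest-remainder rounding, and rows are then sampled uniformly without
replacement within groups. This fixes the total exactly per subset (the
design prescribes 30% per subset) at the cost of a ±1 rounding wobble in
the realized ratio (e.g. 133/17 → empirical ratio 1.96).

MNAR thresholds use the linear-interpolation empirical percentile computed
*per subset*; ties go to the low group ("high" is strictly above the 30th
percentile). With zero-inflated LEMS the threshold is typically 0, so
"high" means any nonzero score — documented behavior, not an artifact. A
fully degenerate variable (empty high group) falls back to MCAR with a
logged warning.

## Little's MCAR test

EM for the incomplete multivariate normal: means initialized to
available-case means, covariance to pairwise available-case covariance
projected to positive semidefinite (eigenvalue floor 1e-8); E-step sweeps
missingness patterns with conditional means/covariances; M-step divides by
n (ML). Convergence when the max-abs parameter change < 1e-6 (≤ 500
iterations); the observed-data log-likelihood is checked to be
non-decreasing. Singular observed blocks are ridge-regularized with a
logged epsilon. Rows missing every variable are dropped with a warning.

The statistic is `d² = Σ_j m_j (ȳ_j − μ̂_[j])' Σ̂_[j]⁻¹ (ȳ_j − μ̂_[j])`
with df = Σ_j p_j − p, referred to the chi-squared upper tail. Patterns
with fewer rows than observed variables still contribute, because the
covariance comes from the pooled EM estimate, not per-pattern. Categorical
inputs are encoded binary → {0,1} and AIS grade → ordinal 1–4 before
testing. Calibration checks: on genuinely multivariate-normal MCAR data
the p-value distribution is uniform (KS < 0.05 at 2000 replicates); on the
zero-inflated synthetic cohort the type-I error stays near the nominal 5%
because pattern means are asymptotically normal regardless of the data's
own distribution.

The mechanism-power test draws its subsets from an n = 5000 synthetic
source cohort rather than the default n = 546: the study design resamples
a *fixed* cohort, so cohort-level binomial noise in, say, the male
fraction is an artifact of the synthetic stand-in, and a larger source
cohort pins the marginals at their nominal values (male fraction SD 0.006
instead of 0.017).

## Imputation engines

- **mean** — unconditional observed mean; deterministic.
- **LOCF** — week-26 donor for the week-52 target (and week-16 for the
  week-26 variant). Donor-missing rows are excluded, reported, and left
  missing; they are dropped from both metrics and the analysis fit.
- **Single imputation** — scikit-learn estimators behind a 5-fold
  grid-search (squared-error loss, shuffled folds seeded per cell).
  Predictors use treatment dummy coding (references AIS A, cervical,
  female); k-NN and SVM pipelines standardize numeric inputs. Default
  grids: k ∈ {1,3,5,10,20}; C ∈ {0.1,1,10,100} (+ γ ∈ {0.001…1} for RBF);
  RF trees ∈ {100,500} × features {√p, all} × leaf {1,5}. The desk
  profile trims the RF grid to 100 trees/√p features to keep hundreds of
  subsets tractable on one CPU; grids live in a replaceable dict.
- **Multiple imputation** (m = 25, one cycle per draw since missingness is
  univariate; an iteration count is exposed for future multivariate use):
  - *pmm*: Bayesian linear regression draw (σ² from a scaled inverse
    chi-squared, β* ~ N(β̂, σ²(X'X)⁻¹)); type-1 matching of predicted
    means (observed rows under β̂, missing rows under β*); one random
    donor from the d = 5 nearest; the donor's observed value is copied.
  - *norm.predict*: the deterministic least-squares prediction; all draws
    coincide by construction (logged as degenerate).
  - *rf*: per draw, a 10-tree forest (min leaf 5) fit on a bootstrap of
    the observed rows; each missing row copies a uniformly drawn donor
    from a random tree's terminal node.
  - Pooling is the per-entry mean of the m draws (pool-then-fit), giving a
    single completed table per method.
- Predictions are clipped to [0, 50] but *not* rounded: LEMS is treated as
  continuous throughout the analysis. pmm/rf draws are observed donor
  values and need no clipping.
- When the target is baseline LEMS, the chronic outcome is excluded from
  the predictors (it is unknowable at baseline); the outcome variable is
  imputed from all other model variables.

## Evaluation

MAE and RMSE are computed over the amputed entries only, against the
vaulted truths, using the pooled value per entry. Ranks are assigned per
subset (ascending metric, ties → average rank) and aggregated to
rank-proportion and mean-rank tables. KS comparisons use the full variable
vectors (observed + imputed); an amputed-positions-only restriction is
available via the metric layer. Asymptotic KS p-values are used despite
integer ties — a documented approximation. The analysis model is OLS with
the same dummy coding; a missing AIS level after complete-case deletion
raises an error naming the level, and the pipeline records that subset's
fit as unavailable rather than aborting (an honest property of CCA under
MNAR with a rare stratum). Beta-difference intervals are 2.5/97.5
percentiles of per-subset (complete − imputed) differences; "biased" means
the interval excludes 0; significance threshold 0.05 throughout.

## Orchestration, seeds, profiles

Every random step derives its seed as `sha256(master_seed | role | cell
coordinates) mod 2³¹`. Hence: subsets depend only on (seed, composition,
index); masks additionally on (target, pattern); method randomness on all
of the above plus the method name. Changing the method list cannot change
the masks, and changing the pattern list cannot change the subset draws —
both properties are tested. Cells are written atomically
(`cells/*.json.tmp` → rename) and reloaded on resume; corrupted cells are
recomputed. The `paper` profile runs 500 subsets per cell; the `desk`
profile runs 100 with the trimmed RF grid (the problem sizes used by the
shipped benchmark tests). Cells are embarrassingly parallel (`--jobs`).

## Known limitations

- The generator's independence assumptions (sex/age/NLI ⊥ severity) damp
  MAR-related signal relative to real data; magnitudes of bias and power
  are condition-specific, directions are the transferable result.
- The week-26 LOCF variant requires a cohort generated without natural
  week-26 gaps, because amputation demands a fully observed target.
- No categorical-variable imputation, no simultaneous missingness in
  several variables, no Rubin's-rules variance pooling (pool-then-fit is
  the deliberate design), no covariance-homogeneity extension of Little's
  test.
- Little's test on mixed binary/ordinal/zero-inflated inputs relies on
  CLT-level normality of pattern means; p-values on tiny subsets or
  near-constant variables should not be over-read.
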