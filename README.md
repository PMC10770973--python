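# scimiss

Simulation framework for studying how missing data and its handling distort
analyses of spinal-cord-injury (SCI) cohorts — and, by extension, any
longitudinal clinical dataset whose outcomes recover toward a plateau.

## The problem

SCI registries and trials collect lower-extremity motor scores (LEMS, an
integer 0–50) at fixed weeks after injury, together with injury severity
(AIS grade A–D), neurological level (cervical/thoracic), age and sex. These
data are heavily zero-inflated (the median LEMS of a predominantly
grade-A cohort is 0 at every time point) and prone to missingness that is
rarely "completely at random". Most published analyses simply drop
incomplete records. This package quantifies what that choice — or any of
ten alternatives — does to the results, using a fully synthetic cohort so
that every "missing" value has a known truth.

The pipeline mirrors a standard simulation design:

1. **Generate** a synthetic complete-case cohort emulating a large acute-SCI
   trial (~79% male, ~74% cervical, age ≈ 32 ± 13, zero-inflated LEMS with
   recovery plateauing between weeks 26 and 52).
2. **Resample** bootstrap subsets of n = 500 with an exactly fixed AIS-grade
   composition (the trial's 325/55/100/20 mix, or balanced 125 × 4).
3. **Ampute** 30% of one LEMS variable under MCAR, MAR (males 2× more
   likely missing) or MNAR (scores above the 30th percentile 4× more
   likely missing), vaulting the true values.
4. **Impute** with: complete-case analysis, mean imputation, last
   observation carried forward (LOCF), CV-tuned single imputation
   (linear regression, k-NN, linear/RBF SVM, random forest), or multiple
   imputation (predictive mean matching, norm.predict, random forest;
   m = 25, pooled by the per-entry mean).
5. **Evaluate** at the population level (two-sample Kolmogorov–Smirnov,
   chi-squared goodness of fit, Little's MCAR test), the individual level
   (MAE/RMSE of imputed vs vaulted values, ranked per subset), and the
   analysis level: bias in the coefficients of the research model

   `LEMS_chronic ~ LEMS_baseline + AIS_grade + NLI + age + sex`

   measured as the mean and 95% percentile interval, over subsets, of the
   difference between complete-data and post-imputation OLS estimates.

Little's MCAR test (EM estimation of a multivariate normal from incomplete
data, pattern-wise d² statistic, chi-squared reference) is implemented from
scratch and verified against closed-form factored-likelihood oracles.

## Worked example

```python
from scimiss import (EMPIRICAL_GRADES, MissingnessSpec, ampute, draw_subset,
                     generate_cohort, mae, rmse, run_method, verify_mechanism)

cohort = generate_cohort(seed=11)        # synthetic complete-case cohort, n=546
subset = draw_subset(cohort, EMPIRICAL_GRADES, 500, seed=7)
amputed = ampute(subset, MissingnessSpec("lems_w52", "MNAR"), seed=3)
print("amputed entries:", amputed.n_amputed)

lt = verify_mechanism(amputed, ["lems_w52", "lems_w0", "age", "sex", "nli", "ais_grade"])
print(f"Little's test: d2={lt.statistic:.1f}, df={lt.df}, p={lt.p_value:.2e}")

for method in ("locf", "mean", "multi_pmm"):
    res = run_method(amputed, method, seed=5)
    truth = amputed.vault.loc[res.pooled.index].astype(float)
    print(f"{method:10s} MAE={mae(truth, res.pooled):5.2f}  RMSE={rmse(truth, res.pooled):5.2f}")
```

prints

```
amputed entries: 150
Little's test: d2=36.3, df=5, p=8.32e-07
locf       MAE= 1.39  RMSE= 2.18
mean       MAE=15.62  RMSE=20.90
multi_pmm  MAE=10.06  RMSE=13.32
```

Exactly 150 of 500 week-52 scores (30%) were blanked; Little's test
correctly rejects the MCAR hypothesis for this MNAR mechanism (p ≪ 0.05).
LOCF — carrying the week-26 score forward across the recovery plateau — is
an order of magnitude more accurate than mean imputation, which replaces a
zero-inflated, wide distribution with a single central value (five LOCF
rows had no week-26 donor and are excluded rather than imputed).

The same experiment at scale runs from the command line:

```sh
scimiss run --profile desk --seed 0 --out bundle/   # 100 subsets per cell
scimiss summarize bundle/
```

producing tidy CSVs of per-subset metrics, rank-proportion tables (rank 1 =
best), Little's-test tallies, and per-coefficient bias summaries. There are
also `scimiss generate`, `scimiss ampute` and `scimiss impute` commands for
single-step use on cohort CSV files.

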