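# mrbee

Bias-corrected multivariable Mendelian randomization (MR) from GWAS summary
statistics.

MR uses genetic variants as instrumental variables (IVs) to estimate causal
effects of exposures on an outcome. With summary statistics, the regression
of outcome associations on exposure associations across IVs (inverse-variance
weighted, IVW) is biased by three mechanisms that standard practice ignores:
the exposure associations are estimated with error (measurement error), that
error is large relative to the signal for weak instruments, and it is
*correlated* with the outcome-side error whenever the exposure and outcome
GWAS share participants (sample overlap). These biases can push causal
estimates in either direction and can drive the false-positive rate for a
truly null effect toward 100% even at sample sizes of ~30k.

This package implements an estimating-equation estimator that removes all
three biases at once. Writing the observed associations as
`bhat_j = beta_j + w_bj`, `ahat_j = alpha_j + w_aj` with per-variant error
covariance blocks `Sigma_wbwb[j]`, `sigma_wbwa[j]` (from the GWAS standard
errors and a cross-study error-correlation matrix estimated from
non-significant variants), the corrected score is

```
psi(theta) = sum_j [ bhat_j (ahat_j - bhat_j' theta)
                     - sigma_wbwa[j] + Sigma_wbwb[j] theta ],
```

which has expectation zero at the true `theta`. Its root is available in
closed form,

```
theta_hat = (Bhat'Bhat - sum_j Sigma_wbwb[j])^-1 (Bhat'alpha_hat - sum_j sigma_wbwa[j]),
```

with sandwich covariance `m^-1 F^-1 V F^-1` (`F` the per-IV Jacobian, `V`
the per-IV score variance). On top of the estimator sit:

- **S_pleio** — a per-variant chi-square(1) test of horizontal pleiotropy
  (outcome association beyond the exposure-mediated prediction), applicable
  to the IV set or genome-wide;
- **Q_pleio** — a chi-square(1) intercept test of globally unbalanced
  pleiotropy (a multivariable analogue of the Egger intercept);
- an **iterative outlier-removal loop** (fit, test every IV, drop flagged
  IVs, refit until the estimate stabilizes) and the FDR-screened **IVW\***
  baseline;
- **closed-form bias predictors** for naive IVW and a concordance diagnostic
  relating predicted bias to observed method differences;
- **multi-outcome joint fitting** with Wald tests of general linear
  hypotheses `C' Theta L = mu` (joint nullity, cross-outcome contrasts);
- a **simulation engine** generating standardized GWAS summary statistics
  with configurable sample sizes, overlap, heritabilities, genetic and
  phenotypic correlations, and planted (optionally outlier-like) UHP/CHP;
- GWAS summary-statistics **I/O**: reading delimited tables, allele
  harmonization across studies, standardization, and threshold + distance
  instrument selection.

## Worked example

`examples/03_simulation_experiment.py` simulates 100 replicate studies at
the reference conditions (1,000 IVs, exposure/outcome GWAS of 20k fully
overlapping participants, phenotypic correlation 0.5, heritability 0.3/0.15,
true effect 0.5) and a null stress test (no causal effect, n=30k, full
overlap). It prints:

```
reference settings (theta = 0.5, full overlap, no pleiotropy):
estimator  mean_estimate  mean_bias  empirical_sd  mean_se  coverage  rejection_rate
    MRBEE         0.5011     0.0011        0.0106   0.0120      0.97             1.0
      IVW         0.5010     0.0010        0.0091   0.0103      0.97             1.0

null effect, n=30k, full overlap (false-positive stress test):
estimator  mean_estimate  mean_bias  empirical_sd  mean_se  coverage  rejection_rate
    MRBEE         0.0008     0.0008        0.0111   0.0113      0.97            0.03
      IVW         0.0509     0.0509        0.0099   0.0099      0.00            1.00
```

In the first block both estimators recover 0.5 — at `theta = 0.5` with full
overlap and phenotypic correlation 0.5 the overlap and attenuation biases of
IVW happen to cancel exactly (the closed-form predictor shows why). The null
block shows the general case: naive IVW is biased upward by the amount the
closed form predicts (0.05) and rejects the true null in 100% of replicates,
while the corrected estimator stays unbiased with a ~5% false-positive rate
and nominal coverage. The other example scripts demonstrate pleiotropy
screening, bias prediction/concordance, and the genome-wide scan with locus
classification (mediation / direct / pleiotropy / novel).

A thin CLI wraps the same library calls:

```
mrbee fixtures --out fx                 # small synthetic panel + error matrix
mrbee fit --panel fx/panel.tsv --error-corr fx/error_correlation.tsv --out fit
mrbee pleio-scan --panel fx/panel.tsv --model fit/model.json \
      --error-corr fx/error_correlation.tsv --out scan
mrbee simulate --replicates 100 --seed 7 --estimators MRBEE,IVW --out sim
mrbee diagnose --panel fx/panel.tsv --model fit/model.json --out diag
```

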