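# Methods

## Model

For m independent instruments, p exposures `x`, and outcome `Y`:

```
x = B'g + U + e_x
Y = theta'x + gamma'g + U + e_Y        =>        alpha = B theta + gamma
```

`B` (m x p) and `alpha` (m) are true standardized associations, `theta` the
direct causal effects, and `gamma` the horizontally pleiotropic effects
(zero for valid instruments). GWAS supply estimates with sampling error,

```
ahat_j = alpha_j + w_aj,   bhat_j = beta_j + w_bj,
(w_aj, w_bj) ~ N(0, [[sigma2_aj, sigma_wbwa_j'], [sigma_wbwa_j, Sigma_wbwb_j]]).
```

The error variances come from the (fixed) GWAS standard errors; the
cross-study error correlations are nonzero under sample overlap, with the
standard closed form `corr = n0 * rho / sqrt(n1 * n2)` for two studies of
sizes n1, n2 sharing n0 participants on phenotypes correlated at rho.

## Estimator

The naive IVW score `sum_j bhat_j (ahat_j - bhat_j' theta)` has expectation
`sum_j sigma_wbwa_j - Sigma_wbwb_j theta` at the truth — nonzero under
overlap or measurement error — which is exactly the bias mechanism. The
corrected score subtracts it:

```
psi(theta) = sum_j bhat_j (ahat_j - bhat_j' theta) - sigma_wbwa_j + Sigma_wbwb_j theta.
```

`psi` is linear in `theta`, so the root is closed-form and the asymptotic
covariance is the sandwich `m^-1 F^-1 V F^-1` with

```
F_hat = m^-1 (Bhat'Bhat - sum_j Sigma_wbwb_j),
V_hat = m^-1 sum_j psi_j(theta_hat) psi_j(theta_hat)'.
```

`V_hat` is deliberately the sum of per-variant outer products: the outer
product of the *summed* score is rank one and cannot estimate the
per-variant score variance that the sandwich requires (it fails the
calibration check below for p > 1). An intercept, when requested, is a
prepended constant predictor with zero measurement error; it estimates the
mean pleiotropic effect `m^-1 sum_j gamma_j`, so Egger-style logic falls out
of the same solver. Per-coefficient p-values use a two-sided normal
reference; all multi-degree tests use chi-square.

Numerical choices: symmetric closed-form solves only (no iteration, no
randomized routines; results are bit-reproducible for fixed inputs); a
condition-number guard (default 1e8) on `F_hat` raises a "correction
exceeds signal" error when the subtracted error covariance makes the
Jacobian near-singular — the over-correction regime of very weak
instruments, where the user should take fewer or stronger IVs.

## Pleiotropy tests

Per variant, `gamma_hat_j = ahat_j - bhat_j' theta_hat` and

```
S_pleio(j) = gamma_hat_j^2 / Upsilon_hat_j ~ chi2(1),
Upsilon_hat_j = sigma2_aj + theta_hat' Sigma_wbwb_j theta_hat
                - 2 theta_hat' sigma_wbwa_j + bhat_j' Cov(theta_hat) bhat_j.
```

The last term is the delta-method propagation of the estimator's
uncertainty and therefore uses `Cov(theta_hat) = m^-1 F^-1 V F^-1` (i.e. an
extra factor m^-1 relative to writing `F^-1 V F^-1` alone); `sigma2_aj` is
the measurement-error variance of `ahat_j` (its squared standard error).
Variants with non-positive `Upsilon_hat` are flagged unusable rather than
silently clipped. Under the null the statistic is chi-square(1); the suite
verifies both the Kolmogorov-Smirnov fit and the 5% type-I rate at m=5000.

`Q_pleio` fits the model with intercept and refers
`theta0_hat^2 / Var(theta0_hat)` to chi-square(1): a test of *unbalanced*
pleiotropy. Symmetric mean-zero pleiotropy leaves it null by construction,
which is why per-IV screening is still needed for outliers.

The iterative removal loop alternates fit, per-IV `S_pleio` against the
fresh estimate, and batch removal of all flagged IVs, until the L1 change
in `theta_hat` is at most tau (default 1e-3) or `max_iterations` (30). The
default removal threshold is chosen per round by Benjamini-Hochberg at FDR
5% over the current IV count — a chi-square(1) quantile corrected for the
number of IVs — rather than a fixed cut; a fixed `xi` can be given. Batch
removal (all flagged at once) is used instead of one-at-a-time: faster and
a fixed point of its own output. `IVW*` is a separate baseline: one
corrected fit, one BH-screened removal, then a plain uncorrected
least-squares fit on the survivors.

## Genome-wide scanning and locus classification

`S_pleio` applies to any variant, not only IVs; the scan computes it
genome-wide with `theta_hat` (and its covariance) taken from the IV-set fit
— the estimator's uncertainty comes from the fit, not the scanned panel.
Lead variants are chosen by smallest `S_pleio` p-value with greedy 1 Mb
distance pruning, kept when significant in either the pleiotropy test or
the marginal GWAS, and classified from three p-values (GWAS, `S_pleio`, and
a joint Wald test of exposure association across the p exposures, using the
exposure-error correlation):

| GWAS | S_pleio | exposure | category |
|------|---------|----------|----------|
| sig  | ns      | (any)    | mediation — outcome association explained through the exposures |
| sig  | sig     | ns       | direct — acts on the outcome, not via modeled exposures |
| sig  | sig     | sig      | pleiotropy — associated with exposures and outcome conditional on them |
| ns   | sig     | (any)    | novel — undetected by the marginal outcome test |

This decision rule is a reconstruction from the prose description of the
four causal diagrams; thresholds (default 5e-8 each) are configurable.

## IVW bias predictors

The bias of naive IVW factorizes as

```
bias(theta_IVW) = {Sigma_BB/m + mean_j Sigma_wbwb_j}^-1
                  * m^-1 {sum_j sigma_wbwa_j - Sigma_wbwb_j theta},
```

a weak-instrument factor times an overlap/measurement-error term (the two
work in opposite directions). The implementation plugs in the observed
second moment `Bhat'Bhat/m` for the first factor, since its expectation is
exactly the bracketed sum. With one exposure, unit variances, and
standardized estimates this specializes to

```
bias = [m / (n1 h2_X + m sigma2_X)] * (n0 sigma_XY / n2 - sigma2_X theta):
```

substitute `Sigma_BB = h2_X`, `Sigma_wbwb = sigma2_X/n1`,
`sigma_wbwa = n0 sigma_XY/(n1 n2)`; the first factor is
`(h2_X/m + sigma2_X/n1)^-1 = m n1/(n1 h2_X + m sigma2_X)` and the second
`n0 sigma_XY/(n1 n2) - sigma2_X theta/n1`, whose product is the display.
The scalar and matrix forms agree to machine precision (a permanent test).
The concordance diagnostic correlates predicted bias with the observed
difference between the screened-IVW and corrected estimates across
exposures; a Pearson r near 1 attributes the method differences to the
known bias sources.

## Error-correlation estimation

At null variants the z-score is pure estimation error, so cross-study
error correlations are estimated as correlations of z-scores over
non-significant variants (default two-sided p > 0.05). Conditioning each
z on |z| < 1.96 truncates the joint normal to a box and *attenuates*
correlations by roughly 15% at rho = 0.5 — material for downstream
corrections — so each pairwise estimate is de-attenuated by numerically
inverting the truncated-bivariate-normal correlation map (Gauss-Legendre
quadrature + Brent root-finding). Selection is per pair by default (the
bivariate inversion is then exact); a jointly-non-significant selection is
available but leaves residual attenuation when a third correlated study
also truncates. The assembled matrix is repaired to the nearest positive
semi-definite correlation matrix by eigenvalue clipping and diagonal
rescaling, since downstream quadratic forms require a valid covariance.
Users may instead supply a matrix directly (identity = assume no overlap).

## Simulation engine

Summary statistics are generated directly on the standardized scale: all
phenotypic and genotypic variances are 1, so the true variance of every
estimate is 1/n. Per-variant true exposure effects are Gaussian
(infinitesimal architecture) with covariance `C/m`,
`C[k,l] = g_corr[k,l] sqrt(h2_k h2_l)`, so the summed squared effects match
the heritabilities in expectation; `alpha = B theta + gamma`. Estimation
errors are multivariate normal across the p+1 studies with the overlap
correlation above, independent across variants. Defaults are the reference
study conditions: m=1000, p=1, n1=n2=20k fully overlapping, phenotypic
correlation 0.5, h2 exposure/outcome 0.3/0.15, theta=0.5, no pleiotropy.

Pleiotropy is planted on random disjoint subsets: UHP draws independent of
the exposure effects (default variance 4/m), CHP draws correlated 0.5 with
the first exposure's effect (the dependence is the defining feature; the
correlation value is a package choice). With `outlier_tails` the draws are
restricted to the two 5% tails of their distribution so planted effects
behave like detectable outliers. Exposure-exposure overlap defaults to
complete (one cohort measuring all exposures) and is configurable.
`pheno_corr` is defined operationally as the correlation entering the
overlap error-correlation formula; how it splits between confounding and
residual correlation is not modeled, and `h2_outcome` is recorded but does
not enter the sampling distribution (which the 1/n rule fixes). What the
generator does *not* emulate: linkage disequilibrium between instruments
(IVs are independent by design, as after LD pruning), allele-frequency
dependent error variances, selection of IVs by significance in the same
data (no winner's curse), or non-Gaussian effect-size architectures — so
passing tests certify the estimator under the stated error model, not
robustness to those realities.

## Problem sizes and tolerances in the test suite

Replicate experiments use 200 replicates (500 for the sandwich-vs-empirical
SD check) at m=1000, matching the reference conditions; Monte-Carlo
tolerances are 3 MC standard errors for means, 3 binomial standard errors
for coverage, 10% relative for the SE calibration, and 1e-8 for the
closed-form vs numeric-root identity. Distributional checks use m=5000
variants.

## Known limitations

- The asymptotics are joint in m and n; with very few instruments the
  normal reference for `theta_hat` and the chi-square reference for
  `S_pleio` degrade, and the condition guard may trigger.
- Distance pruning is a stand-in for LD clumping; no reference panel is
  bundled, and correlated instruments violate the independence assumption.
- The genome-wide scan reuses the IV-set `V_hat`; variance estimates for
  scanned variants far stronger than the IVs are extrapolations.
- CHP that is dense (most IVs) and asymmetric is only addressed by
  including the relevant exposure, not by outlier removal.
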