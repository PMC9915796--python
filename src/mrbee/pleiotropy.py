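"""Horizontal-pleiotropy testing, outlier removal, and genome-wide scanning.

A variant whose outcome association deviates from the fitted
exposure-mediated prediction carries a horizontally pleiotropic effect. The
per-variant statistic

    S_pleio(j) = (ahat_j - bhat_j' theta_hat)^2 / Upsilon_hat_j  ~  chi2(1)

tests that deviation, with Upsilon_hat_j the delta-method variance of the
residual (outcome error variance + theta' Sigma theta - 2 theta' sigma +
bhat' Cov(theta_hat) bhat). On top of it sit: the Q_pleio intercept test for
globally unbalanced pleiotropy; the iterative fit-test-remove loop that
re-estimates causal effects after discarding outlying instruments; the
FDR-screened IVW* baseline; and a genome-wide scan that classifies loci by
the pathway of their association (mediation / direct / pleiotropy / novel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CausalFit, fit_ivw, fit_mrbee
from .errorcov import PerVariantErrorCov
from .exceptions import ClassificationError, OverPruningError, ShapeError
from .io import HarmonizedPanel


def benjamini_hochberg(p_values: np.ndarray, level: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean flags of rejected hypotheses.

    NaN p-values are never flagged and do not count toward the number of
    tests. The flag set is invariant to input order.
    """
    p = np.asarray(p_values, float)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return flags
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    below = ranked <= level * (np.arange(1, n + 1) / n)
    if below.any():
        cutoff = ranked[np.max(np.flatnonzero(below))]
        flags[ok] = pv <= cutoff
    return flags


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(p_values, float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv, kind="stable")
    adj = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    q[ok] = out
    return q


@dataclass
class PleiotropyResult:
    """Per-variant pleiotropy evidence against a fitted causal model."""

    variant_ids: list[str]
    residual: np.ndarray  # (m,) gamma_hat_j
    upsilon: np.ndarray  # (m,) residual variance
    s_pleio: np.ndarray  # (m,) chi-square(1) statistics
    p_values: np.ndarray
    q_values: np.ndarray  # BH-adjusted
    flagged: np.ndarray  # bool, BH at fdr_level
    fdr_level: float = 0.05

    @property
    def m(self) -> int:
        return len(self.variant_ids)


@dataclass
class AlgorithmSettings:
    """Controls for the iterative outlier-removal loop.

    ``xi`` is the removal threshold on S_pleio; with the default ``None``
    the threshold is chosen each round by Benjamini-Hochberg at
    ``fdr_level`` over the current instrument count (a chi-square(1)
    quantile corrected for the number of IVs). ``tau`` is the L1
    convergence tolerance on the causal estimate.
    """

    xi: float | None = None
    fdr_level: float = 0.05
    tau: float = 1e-3
    max_iterations: int = 30

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.xi is not None and self.xi <= 0:
            raise ValueError("xi must be positive")


@dataclass
class IMRPResult:
    fit: CausalFit
    removed: list[str]
    n_iterations: int
    converged: bool


@dataclass
class QPleioResult:
    statistic: float
    p_value: float
    fit: CausalFit  # the intercept-augmented fit

    def __iter__(self):  # allows `stat, p, fit = qpleio(...)`
        return iter((self.statistic, self.p_value, self.fit))


@dataclass
class LocusCall:
    """One genomic locus summarized by its lead variant, with the pathway
    classification implied by GWAS, pleiotropy, and exposure evidence."""

    lead_variant: str
    gwas_p: float
    spleio_p: float
    exposure_p: float
    category: str | None = None
    chromosome: str | None = None
    position: int | None = None


def spleio(
    panel: HarmonizedPanel,
    fit: CausalFit,
    ecov: PerVariantErrorCov,
    fdr_level: float = 0.05,
) -> PleiotropyResult:
    """Per-variant pleiotropy test against a fitted causal model.

    May be applied to the IV set or to a much larger (e.g. genome-wide)
    panel; the uncertainty of theta_hat always comes from ``fit``. Variants
    with non-positive estimated residual variance are unusable and reported
    with NaN statistics (a warning counts them).
    """
    if ecov.m != panel.m:
        raise ShapeError("ecov blocks do not match the panel")
    B = panel.exposure_estimates
    alpha = panel.outcome_estimates
    if alpha.ndim != 1:
        raise ShapeError("spleio needs a single-outcome panel")
    theta = fit.theta
    resid = alpha - B @ theta
    if fit.has_intercept:
        resid = resid - fit.theta0
        B_aug = np.hstack([np.ones((panel.m, 1)), B])
    else:
        B_aug = B

    sigma_aa = ecov.sigma_aa
    quad_theta = np.einsum("l,jlk,k->j", theta, ecov.sigma_bb, theta)
    cross = 2.0 * ecov.sigma_ba @ theta
    # fit.covariance already is m^-1 F^-1 V F^-1 = Cov(theta_hat)
    fit_var = np.einsum("jk,kl,jl->j", B_aug, fit.covariance, B_aug)
    upsilon = sigma_aa + quad_theta + fit_var - cross

    bad = upsilon <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} variants have non-positive residual "
                      "variance and are unusable in S_pleio", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(bad, np.nan, resid**2 / upsilon)
    pvals = np.where(np.isnan(s), np.nan, stats.chi2.sf(s, df=1))
    qvals = bh_qvalues(pvals)
    flagged = benjamini_hochberg(pvals, fdr_level)
    return PleiotropyResult(list(panel.variant_ids), resid, upsilon, s, pvals,
                            qvals, flagged, fdr_level)


def qpleio(
    panel: HarmonizedPanel,
    ecov: PerVariantErrorCov,
) -> QPleioResult:
    """Global test of unbalanced horizontal pleiotropy.

    Fits the bias-corrected model with an intercept — which estimates the
    mean pleiotropic effect m^-1 sum_j gamma_j — and refers the squared
    intercept over its sandwich variance to chi-square(1).
    """
    if panel.m <= panel.p + 2:
        raise ShapeError("Q_pleio needs m > p + 2 instruments")
    fit = fit_mrbee(panel, ecov, intercept=True)
    var0 = float(fit.covariance[0, 0])
    statistic = float(fit.theta0**2 / var0)
    return QPleioResult(statistic, float(stats.chi2.sf(statistic, df=1)), fit)


def imrp_loop(
    panel: HarmonizedPanel,
    ecov: PerVariantErrorCov,
    settings: AlgorithmSettings | None = None,
    intercept: bool = False,
) -> IMRPResult:
    """Iterative fit / pleiotropy-test / removal of outlying instruments.

    Each round fits the bias-corrected estimator on the retained set, tests
    every retained instrument with S_pleio against the fresh estimate, and
    removes all instruments exceeding the threshold at once; iteration stops
    when the L1 change in the causal estimate is at most ``tau`` (removing
    nothing is a fixed point). Hitting ``max_iterations`` returns the last
    iterate with a non-convergence warning.
    """
    settings = settings or AlgorithmSettings()
    retained = np.arange(panel.m)
    fit = fit_mrbee(panel, ecov, intercept=intercept)
    n_iter = 0
    converged = False
    for n_iter in range(1, settings.max_iterations + 1):
        sub_panel = panel.subset(retained)
        sub_ecov = ecov.subset(retained)
        result = spleio(sub_panel, fit, sub_ecov, fdr_level=settings.fdr_level)
        if settings.xi is None:
            drop = result.flagged
        else:
            with np.errstate(invalid="ignore"):
                drop = np.nan_to_num(result.s_pleio, nan=0.0) > settings.xi
        n_keep = int((~drop).sum())
        if n_keep <= panel.p + 1:
            raise OverPruningError(
                f"removal would leave {n_keep} instruments for p={panel.p} exposures")
        retained = retained[~drop]
        new_fit = fit_mrbee(panel.subset(retained), ecov.subset(retained),
                            intercept=intercept)
        change = float(np.abs(new_fit.theta - fit.theta).sum())
        fit = new_fit
        if change <= settings.tau:
            converged = True
            break
    if not converged:
        warnings.warn(f"IMRP did not converge in {settings.max_iterations} "
                      "iterations; returning the last iterate", stacklevel=2)
    removed = sorted(set(panel.variant_ids) - {panel.variant_ids[i] for i in retained})
    return IMRPResult(fit, removed, n_iter, converged)


def fit_ivw_star(
    panel: HarmonizedPanel,
    ecov: PerVariantErrorCov,
    fdr_level: float = 0.05,
) -> CausalFit:
    """Pleiotropy-screened IVW: the robust baseline.

    Screens instruments with S_pleio under the bias-corrected fit,
    Benjamini-Hochberg at ``fdr_level``, removes flagged instruments, then
    fits *plain* IVW (no measurement-error correction) on the survivors.
    """
    fit = fit_mrbee(panel, ecov)
    result = spleio(panel, fit, ecov, fdr_level=fdr_level)
    keep = ~result.flagged
    if int(keep.sum()) <= panel.p + 1:
        raise OverPruningError("pleiotropy screen removed too many instruments")
    return fit_ivw(panel.subset(keep), method_tag="IVW_star")


def classify_loci(
    calls: list[LocusCall],
    alpha_gwas: float = 5e-8,
    alpha_pleio: float = 5e-8,
    alpha_exposure: float = 5e-8,
) -> list[LocusCall]:
    """Assign each locus a pathway category from its three p-values.

    * ``mediation`` — GWAS-significant but no residual pleiotropy: the
      outcome association is explained through the modeled exposures.
    * ``direct`` — GWAS-significant with residual pleiotropy but no
      exposure association: the locus acts on the outcome directly.
    * ``pleiotropy`` — all three significant: simultaneous association with
      the exposures and with the outcome conditional on them.
    * ``novel`` — residual pleiotropy without genome-wide GWAS evidence: a
      locus undetected by the marginal outcome test.

    This decision rule is a reconstruction from the prose description of
    the four causal diagrams; exact thresholds are configurable.
    """
    out = []
    for call in calls:
        for name, v in (("gwas_p", call.gwas_p), ("spleio_p", call.spleio_p),
                        ("exposure_p", call.exposure_p)):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ClassificationError(f"locus {call.lead_variant}: missing {name}")
        g = call.gwas_p < alpha_gwas
        s = call.spleio_p < alpha_pleio
        e = call.exposure_p < alpha_exposure
        if g and not s:
            cat = "mediation"
        elif g and s and not e:
            cat = "direct"
        elif g and s and e:
            cat = "pleiotropy"
        elif not g and s:
            cat = "novel"
        else:
            raise ClassificationError(
                f"locus {call.lead_variant} is significant in neither GWAS nor "
                "pleiotropy testing and is not a locus")
        out.append(LocusCall(call.lead_variant, call.gwas_p, call.spleio_p,
                             call.exposure_p, cat, call.chromosome, call.position))
    return out


def _joint_exposure_p(panel: HarmonizedPanel, ecov: PerVariantErrorCov) -> np.ndarray:
    """Joint Wald p-value across the p exposures per variant (chi2(p))."""
    z = panel.exposure_estimates / panel.exposure_ses
    p = panel.p
    # error-correlation of the exposure estimates, from any nonzero block
    R = np.eye(p)
    d = np.sqrt(np.diagonal(ecov.sigma_bb, axis1=1, axis2=2))
    ok = (d > 0).all(axis=1)
    if ok.any():
        j = int(np.flatnonzero(ok)[0])
        R = ecov.sigma_bb[j] / np.outer(d[j], d[j])
    Rinv = np.linalg.inv(R)
    stat = np.einsum("jk,kl,jl->j", z, Rinv, z)
    return stats.chi2.sf(stat, df=p)


def genome_scan(
    panel: HarmonizedPanel,
    fit: CausalFit,
    ecov: PerVariantErrorCov,
    window_bp: int = 1_000_000,
    alpha_gwas: float = 5e-8,
    alpha_pleio: float = 5e-8,
    alpha_exposure: float = 5e-8,
) -> list[LocusCall]:
    """Genome-wide pleiotropy scan with locus classification.

    Computes S_pleio for every variant in ``panel`` (typically much larger
    than the IV set used to obtain ``fit``), selects lead variants by
    smallest S_pleio p-value with greedy distance pruning at ``window_bp``,
    keeps loci significant in either the pleiotropy test or the marginal
    GWAS, and classifies each.
    """
    result = spleio(panel, fit, ecov)
    if panel.outcome_pvalues is not None and not np.isnan(panel.outcome_pvalues).any():
        gwas_p = panel.outcome_pvalues
    else:
        zy = np.abs(panel.outcome_estimates / panel.outcome_ses)
        gwas_p = 2.0 * stats.norm.sf(zy)
    exposure_p = _joint_exposure_p(panel, ecov)

    with np.errstate(invalid="ignore"):
        candidate = ((np.nan_to_num(result.p_values, nan=1.0) < alpha_pleio)
                     | (gwas_p < alpha_gwas))
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return []
    order = idx[np.argsort(np.nan_to_num(result.p_values[idx], nan=1.0), kind="stable")]
    leads: list[int] = []
    for i in order:
        if panel.chromosomes is None or panel.positions is None:
            leads.append(int(i))
            continue
        ci, xi = panel.chromosomes[i], int(panel.positions[i])
        if all(panel.chromosomes[j] != ci or abs(int(panel.positions[j]) - xi) > window_bp
               for j in leads):
            leads.append(int(i))
    calls = [LocusCall(
        lead_variant=panel.variant_ids[i],
        gwas_p=float(gwas_p[i]),
        spleio_p=float(result.p_values[i]),
        exposure_p=float(exposure_p[i]),
        chromosome=None if panel.chromosomes is None else str(panel.chromosomes[i]),
        position=None if panel.positions is None else int(panel.positions[i]),
    ) for i in leads]
    return classify_loci(calls, alpha_gwas, alpha_pleio, alpha_exposure)
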