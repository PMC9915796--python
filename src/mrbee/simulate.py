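"""Simulation of GWAS summary statistics for MR method evaluation.

Summary statistics are generated directly on the standardized scale: all
phenotypic and genotypic variances are 1, so the true sampling variance of
every per-variant estimate is the reciprocal of its GWAS sample size. True
exposure effects are drawn from an infinitesimal (Gaussian) architecture
whose per-variant covariance is set by the exposure heritabilities and
genetic correlations; the true outcome effect of each variant is the
exposure-mediated part plus any planted horizontally pleiotropic effect.
Estimation errors are multivariate normal across the p+1 studies with
cross-study correlation n0 * rho / sqrt(n_a * n_b) induced by sample
overlap, independent across variants.

The replicate driver fits any subset of the implemented estimators and
tabulates bias, coverage, and rejection rates, reproducibly from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import CausalFit, fit_ivw, fit_mrbee
from .errorcov import (
    ErrorCorrelationMatrix,
    PerVariantErrorCov,
    expand_to_covariances,
    theoretical_overlap_correlation,
)
from .exceptions import ConfigurationError, DomainError
from .io import HarmonizedPanel
from .pleiotropy import AlgorithmSettings, fit_ivw_star, imrp_loop

ESTIMATOR_TAGS = ("IVW", "MRBEE", "MRBEE_IMRP", "IVW_star")
_Z975 = float(stats.norm.ppf(0.975))
_TAIL_Z = float(stats.norm.ppf(0.95))  # draws restricted to the two 5% tails


def _corr_default(k: int, off: float) -> np.ndarray:
    c = np.full((k, k), off)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SimulationConfig:
    """Generative settings for one simulated MR study.

    Defaults reproduce the reference univariable study conditions: 1,000
    instruments, exposure and outcome GWAS of 20k fully overlapping
    participants, phenotypic correlation 0.5, exposure heritability 0.3
    (outcome 0.15), true causal effect 0.5, no pleiotropy. Pleiotropy is
    planted by making gamma nonzero for a random fraction of instruments:
    UHP draws are independent of the exposure effects, CHP draws are
    correlated with the first exposure's effects (0.5 by default); with
    ``outlier_tails`` the draws are restricted to the two 5% tails of their
    distribution so the planted effects behave like outliers.
    """

    m: int = 1000
    p: int = 1
    n_exposure: np.ndarray | int = 20_000
    n_outcome: int = 20_000
    n_overlap: np.ndarray | int | None = None  # default: full overlap
    h2_exposure: np.ndarray | float = 0.3
    h2_outcome: float = 0.15
    pheno_corr: np.ndarray | float = 0.5  # (p+1, p+1) or scalar off-diagonal
    genetic_corr: np.ndarray | float = 0.5  # (p, p) or scalar off-diagonal
    theta_true: np.ndarray | float = 0.5
    uhp_fraction: float = 0.0
    uhp_variance: float | None = None  # default 4/m
    chp_fraction: float = 0.0
    chp_variance: float | None = None  # default 4/m
    chp_beta_corr: float = 0.5
    outlier_tails: bool = False
    exposure_overlap: str = "complete"  # complete | none
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_exposure = np.broadcast_to(np.asarray(self.n_exposure, int),
                                          (self.p,)).copy()
        if self.n_overlap is None:
            self.n_overlap = np.minimum(self.n_exposure, self.n_outcome)
        self.n_overlap = np.broadcast_to(np.asarray(self.n_overlap, int),
                                         (self.p,)).copy()
        if (self.n_overlap > np.minimum(self.n_exposure, self.n_outcome)).any():
            raise DomainError("n_overlap exceeds min(n_exposure, n_outcome)")
        self.h2_exposure = np.broadcast_to(np.asarray(self.h2_exposure, float),
                                           (self.p,)).copy()
        if ((self.h2_exposure < 0) | (self.h2_exposure > 1)).any():
            raise DomainError("h2_exposure must be in [0, 1]")
        if not (0 <= self.h2_outcome < 1):
            raise DomainError("h2_outcome must be in [0, 1)")
        self.theta_true = np.broadcast_to(np.asarray(self.theta_true, float),
                                          (self.p,)).copy()
        if np.isscalar(self.pheno_corr) or np.ndim(self.pheno_corr) == 0:
            self.pheno_corr = _corr_default(self.p + 1, float(self.pheno_corr))
        self.pheno_corr = np.asarray(self.pheno_corr, float)
        if np.isscalar(self.genetic_corr) or np.ndim(self.genetic_corr) == 0:
            self.genetic_corr = _corr_default(self.p, float(self.genetic_corr))
        self.genetic_corr = np.asarray(self.genetic_corr, float)
        for name, c, k in (("pheno_corr", self.pheno_corr, self.p + 1),
                           ("genetic_corr", self.genetic_corr, self.p)):
            if c.shape != (k, k):
                raise DomainError(f"{name} must be {k}x{k}")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise DomainError(f"{name} must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise DomainError(f"{name} is not positive semi-definite")
        for name, frac in (("uhp_fraction", self.uhp_fraction),
                           ("chp_fraction", self.chp_fraction)):
            if not (0 <= frac < 1):
                raise DomainError(f"{name} must be in [0, 1)")
        if self.uhp_fraction + self.chp_fraction >= 1:
            raise DomainError("uhp_fraction + chp_fraction must be < 1")
        if self.exposure_overlap not in ("complete", "none"):
            raise ConfigurationError("exposure_overlap must be 'complete' or 'none'")

    @property
    def uhp_var(self) -> float:
        return 4.0 / self.m if self.uhp_variance is None else float(self.uhp_variance)

    @property
    def chp_var(self) -> float:
        return 4.0 / self.m if self.chp_variance is None else float(self.chp_variance)

    def error_correlation(self) -> ErrorCorrelationMatrix:
        """Overlap-induced correlation of estimation errors across studies."""
        k = self.p + 1
        n = np.concatenate([self.n_exposure, [self.n_outcome]])
        corr = np.eye(k)
        for a in range(k):
            for b in range(a + 1, k):
                if a < self.p and b < self.p:  # exposure pair
                    n0 = (min(n[a], n[b]) if self.exposure_overlap == "complete"
                          else 0)
                elif b == self.p:  # exposure a vs outcome
                    n0 = int(self.n_overlap[a])
                corr[a, b] = corr[b, a] = theoretical_overlap_correlation(
                    int(n[a]), int(n[b]), int(n0), float(self.pheno_corr[a, b]))
        return ErrorCorrelationMatrix(corr)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class SimulatedStudy:
    """One simulated study: the observed panel plus its generating truth."""

    panel: HarmonizedPanel
    true_beta: np.ndarray  # (m, p)
    true_alpha: np.ndarray  # (m,)
    true_gamma: np.ndarray  # (m,)
    ecov_true: PerVariantErrorCov
    config: SimulationConfig


def _tail_normal(rng: np.random.Generator, size: int) -> np.ndarray:
    """Standard-normal draws restricted to the two 5% tails."""
    u = rng.uniform(0.0, 0.05, size=size)
    z = stats.norm.ppf(u)  # lower 5% tail
    sign = rng.choice([-1.0, 1.0], size=size)
    return sign * np.abs(z)


def draw_true_effects(
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw true exposure effects and planted pleiotropic effects.

    Exposure-effect rows are i.i.d. multivariate normal with covariance
    C/m where C[k,l] = genetic_corr[k,l] * sqrt(h2_k * h2_l), so the summed
    squared effects have expectation h2_k per exposure. Pleiotropy is
    planted on disjoint random UHP and CHP instrument subsets.
    """
    h = np.sqrt(config.h2_exposure)
    C = config.genetic_corr * np.outer(h, h) / config.m
    if np.allclose(C, 0.0):
        true_beta = np.zeros((config.m, config.p))
    else:
        L = np.linalg.cholesky(C + 1e-14 * np.eye(config.p))
        true_beta = rng.standard_normal((config.m, config.p)) @ L.T

    gamma = np.zeros(config.m)
    u = rng.uniform(size=config.m)
    is_uhp = u < config.uhp_fraction
    is_chp = (~is_uhp) & (u < config.uhp_fraction + config.chp_fraction)

    n_uhp = int(is_uhp.sum())
    if n_uhp:
        z = (_tail_normal(rng, n_uhp) if config.outlier_tails
             else rng.standard_normal(n_uhp))
        gamma[is_uhp] = np.sqrt(config.uhp_var) * z

    n_chp = int(is_chp.sum())
    if n_chp:
        # CHP: gamma correlated with the first exposure's true effect
        rho = config.chp_beta_corr
        sd_b1 = np.sqrt(config.h2_exposure[0] / config.m)
        base = rho * np.sqrt(config.chp_var) * true_beta[is_chp, 0] / sd_b1
        indep_sd = np.sqrt((1.0 - rho**2) * config.chp_var)
        g = base + indep_sd * rng.standard_normal(n_chp)
        if config.outlier_tails:
            # rejection-sample the independent component until each draw
            # lands in the tails of gamma's marginal distribution
            cut = _TAIL_Z * np.sqrt(config.chp_var)
            for _ in range(1000):
                bad = np.abs(g) <= cut
                if not bad.any():
                    break
                g[bad] = base[bad] + indep_sd * rng.standard_normal(int(bad.sum()))
        gamma[is_chp] = g
    return true_beta, gamma


def draw_summary_stats(
    true_beta: np.ndarray,
    true_gamma: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedStudy:
    """Draw observed summary statistics around the given truth.

    Per variant, the (p+1)-vector of estimates is multivariate normal
    centered at (beta_j, alpha_j = beta_j' theta + gamma_j) with per-study
    variances 1/n and overlap-induced cross-study covariances, independent
    across variants.
    """
    m, p = true_beta.shape
    if (m, p) != (config.m, config.p):
        raise DomainError("truth does not conform with the configuration")
    true_alpha = true_beta @ config.theta_true + true_gamma

    corr = config.error_correlation()
    se = 1.0 / np.sqrt(np.concatenate([config.n_exposure, [config.n_outcome]]))
    cov = corr.matrix * np.outer(se, se)
    L = np.linalg.cholesky(cov + 1e-16 * np.eye(p + 1))
    W = rng.standard_normal((m, p + 1)) @ L.T

    beta_hat = true_beta + W[:, :p]
    alpha_hat = true_alpha + W[:, p]
    exposure_ses = np.tile(se[:p], (m, 1))
    outcome_ses = np.full(m, se[p])
    zx = beta_hat / exposure_ses
    zy = alpha_hat / outcome_ses

    chroms = np.array([str(j % 22 + 1) for j in range(m)])
    positions = np.array([1 + (j // 22) * 2_000_000 for j in range(m)])
    panel = HarmonizedPanel(
        variant_ids=[f"rs{j + 1}" for j in range(m)],
        exposure_estimates=beta_hat,
        outcome_estimates=alpha_hat,
        exposure_ses=exposure_ses,
        outcome_ses=outcome_ses,
        exposure_names=[f"exposure{k + 1}" for k in range(p)],
        standardization="by_se_sqrt_n",
        chromosomes=chroms,
        positions=positions,
        exposure_n=np.tile(config.n_exposure.astype(float), (m, 1)),
        outcome_n=np.full(m, float(config.n_outcome)),
        exposure_pvalues=2.0 * stats.norm.sf(np.abs(zx)),
        outcome_pvalues=2.0 * stats.norm.sf(np.abs(zy)),
    )
    ecov_true = expand_to_covariances(corr, panel)
    return SimulatedStudy(panel, true_beta, true_alpha, true_gamma, ecov_true, config)


def simulate_study(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> SimulatedStudy:
    """Draw truth and summary statistics in one call (seeded)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    true_beta, true_gamma = draw_true_effects(config, rng)
    return draw_summary_stats(true_beta, true_gamma, config, rng)


def _fit_one(tag: str, study: SimulatedStudy) -> CausalFit:
    if tag == "IVW":
        return fit_ivw(study.panel)
    if tag == "MRBEE":
        return fit_mrbee(study.panel, study.ecov_true)
    if tag == "MRBEE_IMRP":
        return imrp_loop(study.panel, study.ecov_true, AlgorithmSettings()).fit
    if tag == "IVW_star":
        return fit_ivw_star(study.panel, study.ecov_true)
    raise ConfigurationError(
        f"unknown estimator tag {tag!r}; choose from {ESTIMATOR_TAGS}")


@dataclass
class ExperimentResult:
    """Replicate-level estimates and their aggregation."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def run_experiment(
    config: SimulationConfig,
    estimators: tuple[str, ...] = ("MRBEE",),
    replicates: int = 200,
    seed: int | None = None,
) -> ExperimentResult:
    """Run a replicate experiment and tabulate bias, coverage, and power.

    Per estimator and replicate records the estimate, sandwich SE, whether
    the nominal 95% interval covers the truth, and whether the two-sided
    test of zero effect rejects at 0.05; the summary aggregates mean bias,
    relative bias, empirical SD, mean SE, coverage, and rejection rate.
    Fully reproducible from ``seed`` (defaults to ``config.seed``).
    """
    if replicates < 2:
        raise ConfigurationError("need at least 2 replicates")
    for tag in estimators:
        if tag not in ESTIMATOR_TAGS:
            raise ConfigurationError(
                f"unknown estimator tag {tag!r}; choose from {ESTIMATOR_TAGS}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for r in range(replicates):
        study = simulate_study(config, rng)
        for tag in estimators:
            fit = _fit_one(tag, study)
            for k in range(config.p):
                est, se = float(fit.theta[k]), float(fit.exposure_se[k])
                truth = float(config.theta_true[k])
                rows.append({
                    "estimator": tag, "replicate": r, "exposure": k + 1,
                    "theta_true": truth, "theta_hat": est, "se": se,
                    "covers": abs(est - truth) <= _Z975 * se,
                    "rejects": float(fit.exposure_p_values[k]) < 0.05,
                    "m_used": fit.m_used,
                })
    rep = pd.DataFrame(rows)
    g = rep.groupby(["estimator", "exposure"], sort=False)
    summary = g.agg(
        theta_true=("theta_true", "first"),
        mean_estimate=("theta_hat", "mean"),
        empirical_sd=("theta_hat", "std"),
        mean_se=("se", "mean"),
        coverage=("covers", "mean"),
        rejection_rate=("rejects", "mean"),
        n_replicates=("replicate", "count"),
    ).reset_index()
    summary["mean_bias"] = summary["mean_estimate"] - summary["theta_true"]
    with np.errstate(divide="ignore", invalid="ignore"):
        summary["relative_bias_pct"] = np.where(
            summary["theta_true"] != 0,
            summary["mean_bias"] / summary["theta_true"] * 100.0, np.nan)
    summary["mc_se"] = summary["empirical_sd"] / np.sqrt(summary["n_replicates"])
    return ExperimentResult(rep, summary, config)
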