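"""Bias-corrected estimating equations for multivariable MR.

The naive multivariable IVW estimator regresses outcome associations on
exposure associations across instruments; because the exposure associations
are themselves estimated with error — error that is correlated with the
outcome side whenever samples overlap — its score function has nonzero
expectation and the estimate is biased. The corrected score subtracts the
exact expectation of that error contribution,

    psi(theta) = sum_j [ bhat_j (ahat_j - bhat_j' theta)
                         - sigma_wb_wa[j] + Sigma_wb_wb[j] theta ],

whose root has a closed form and is asymptotically normal with sandwich
covariance m^-1 F^-1 V F^-1, where F is the expected negative Jacobian per
instrument and V the per-instrument score variance. All of that machinery
lives here, together with the plain IVW baseline (the same solver with zero
error covariance), multi-outcome joint fitting, and Wald tests of general
linear hypotheses C' Theta L = mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errorcov import PerVariantErrorCov
from .exceptions import (
    AlignmentError,
    HypothesisDegeneracyError,
    ShapeError,
    SingularCorrectionError,
)
from .io import HarmonizedPanel

#: condition-number guard on the corrected Jacobian
DEFAULT_CONDITION_LIMIT = 1e8


@dataclass
class CausalFit:
    """A fitted set of direct causal effects with sandwich uncertainty.

    When an intercept is included it occupies index 0 of ``covariance``,
    ``se`` and ``p_values``; ``theta`` always holds the exposure
    coefficients only, with the intercept reported separately as ``theta0``.
    """

    theta: np.ndarray  # (p,)
    theta0: float | None
    covariance: np.ndarray  # (d, d), d = p (+1 with intercept)
    F_hat: np.ndarray  # (d, d)
    V_hat: np.ndarray  # (d, d)
    m_used: int
    se: np.ndarray  # (d,)
    p_values: np.ndarray  # (d,)
    method_tag: str  # IVW | IVW_star | MRBEE
    exposure_names: list[str] = field(default_factory=list)
    psi: np.ndarray | None = None  # (m, d) retained score contributions

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def has_intercept(self) -> bool:
        return self.theta0 is not None

    @property
    def exposure_se(self) -> np.ndarray:
        return self.se[1:] if self.has_intercept else self.se

    @property
    def exposure_p_values(self) -> np.ndarray:
        return self.p_values[1:] if self.has_intercept else self.p_values

    @property
    def theta0_se(self) -> float:
        if not self.has_intercept:
            raise ValueError("fit has no intercept")
        return float(self.se[0])

    def to_json(self, path) -> None:
        """Serialize the fit (without per-variant scores) to JSON."""
        import json

        data = {
            "theta": self.theta.tolist(), "theta0": self.theta0,
            "covariance": self.covariance.tolist(), "F_hat": self.F_hat.tolist(),
            "V_hat": self.V_hat.tolist(), "m_used": self.m_used,
            "se": self.se.tolist(), "p_values": self.p_values.tolist(),
            "method_tag": self.method_tag, "exposure_names": self.exposure_names,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CausalFit":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(theta=np.asarray(d["theta"]), theta0=d["theta0"],
                   covariance=np.asarray(d["covariance"]),
                   F_hat=np.asarray(d["F_hat"]), V_hat=np.asarray(d["V_hat"]),
                   m_used=int(d["m_used"]), se=np.asarray(d["se"]),
                   p_values=np.asarray(d["p_values"]), method_tag=d["method_tag"],
                   exposure_names=list(d["exposure_names"]))

    def summary(self) -> "pd.DataFrame":  # noqa: F821 - runtime import
        import pandas as pd

        names = list(self.exposure_names) or [f"exposure{k + 1}" for k in range(self.p)]
        if self.has_intercept:
            names = ["(intercept)"] + names
            est = np.concatenate([[self.theta0], self.theta])
        else:
            est = self.theta
        return pd.DataFrame({"term": names, "estimate": est, "se": self.se,
                             "p_value": self.p_values, "method": self.method_tag})


@dataclass
class MultiOutcomeFit:
    """Joint fit of the same exposures on q outcomes with one IV set.

    ``theta`` is the d x q coefficient matrix (intercept row first when
    present); ``covariance`` is the (d*q) x (d*q) covariance of
    vec(theta) in column-stacking order, so hypothesis tests on any linear
    combination across outcomes are quadratic forms in it.
    """

    theta: np.ndarray  # (d, q)
    covariance: np.ndarray  # (d*q, d*q), vec (column-major) order
    F_hat: np.ndarray
    m_used: int
    has_intercept: bool
    method_tag: str
    fits: list[CausalFit] = field(default_factory=list)  # per-outcome

    @property
    def d(self) -> int:
        return self.theta.shape[0]

    @property
    def q(self) -> int:
        return self.theta.shape[1]


@dataclass
class HypothesisSpec:
    """General linear hypothesis C' Theta L = mu on a stacked fit.

    ``C`` (d x h) selects/combines coefficient rows, ``L`` (q x l) combines
    outcome columns, and ``mu`` (h x l) is the hypothesized value. The Wald
    statistic is referred to chi-square with h*l degrees of freedom.
    """

    C: np.ndarray
    L: np.ndarray
    mu: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, float))
        self.L = np.atleast_2d(np.asarray(self.L, float))
        self.mu = np.atleast_2d(np.asarray(self.mu, float))
        if self.mu.shape != (self.C.shape[1], self.L.shape[1]):
            raise ShapeError(
                f"mu must be {self.C.shape[1]}x{self.L.shape[1]}, got {self.mu.shape}")


def _outcome_vector(panel: HarmonizedPanel) -> np.ndarray:
    a = panel.outcome_estimates
    if a.ndim != 1:
        raise ShapeError("panel has multiple outcome columns; use fit_multivariate")
    return a


def ivw_score(theta: np.ndarray, panel: HarmonizedPanel) -> np.ndarray:
    """Naive IVW score B'(alpha - B theta): gradient of half squared error."""
    theta = np.asarray(theta, float)
    B = panel.exposure_estimates
    alpha = _outcome_vector(panel)
    if theta.shape != (B.shape[1],):
        raise ShapeError(f"theta must have length {B.shape[1]}, got {theta.shape}")
    # summed per-variant, matching the corrected score's summation order so
    # the zero-covariance degeneracy is bit-exact
    return (B * (alpha - B @ theta)[:, None]).sum(axis=0)


def score_contributions(
    theta: np.ndarray,
    B: np.ndarray,
    alpha: np.ndarray,
    ecov: PerVariantErrorCov,
) -> np.ndarray:
    """Per-variant bias-corrected score contributions psi_j(theta), (m, d)."""
    resid = alpha - B @ theta
    return (B * resid[:, None] - ecov.sigma_ba
            + np.einsum("jkl,l->jk", ecov.sigma_bb, theta))


def mrbee_score(
    theta: np.ndarray,
    panel: HarmonizedPanel,
    ecov: PerVariantErrorCov,
) -> np.ndarray:
    """Bias-corrected score psi(theta) summed over instruments.

    With all error-covariance blocks zero this reduces exactly to
    :func:`ivw_score`.
    """
    theta = np.asarray(theta, float)
    B = panel.exposure_estimates
    alpha = _outcome_vector(panel)
    if ecov.m != panel.m:
        raise ShapeError(f"ecov has {ecov.m} blocks, panel has {panel.m} variants")
    if ecov.p != panel.p or theta.shape != (panel.p,):
        raise ShapeError("exposure dimension mismatch between theta, panel and ecov")
    if ecov.sigma_ba.ndim != 2:
        raise ShapeError("mrbee_score needs single-outcome covariance blocks")
    return score_contributions(theta, B, alpha, ecov).sum(axis=0)


def _augment_intercept(B: np.ndarray, ecov: PerVariantErrorCov) -> tuple[np.ndarray, PerVariantErrorCov]:
    """Prepend a constant column with zero measurement error (intercept)."""
    m, p = B.shape
    Ba = np.hstack([np.ones((m, 1)), B])
    bb = np.zeros((m, p + 1, p + 1))
    bb[:, 1:, 1:] = ecov.sigma_bb
    if ecov.sigma_ba.ndim == 2:
        ba = np.hstack([np.zeros((m, 1)), ecov.sigma_ba])
    else:
        ba = np.concatenate([np.zeros((m, 1, ecov.sigma_ba.shape[2])), ecov.sigma_ba],
                            axis=1)
    return Ba, PerVariantErrorCov(bb, ba, ecov.sigma_aa)


def _solve_one(
    B: np.ndarray,
    alpha: np.ndarray,
    sigma_bb_sum: np.ndarray,
    sigma_ba_sum: np.ndarray,
    condition_limit: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form root of psi and the Jacobian estimate F_hat."""
    m = B.shape[0]
    A = B.T @ B - sigma_bb_sum
    A = (A + A.T) / 2.0
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > condition_limit:
        raise SingularCorrectionError(
            f"corrected Jacobian has condition number {cond:.3g} "
            f"(> {condition_limit:.0g}): the measurement-error correction "
            "exceeds the instrument signal; use fewer or stronger IVs")
    theta = np.linalg.solve(A, B.T @ alpha - sigma_ba_sum)
    return theta, A / m


def _sandwich(F_hat: np.ndarray, psi: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    V_hat = psi.T @ psi / m
    Finv = np.linalg.inv(F_hat)
    cov = Finv @ V_hat @ Finv / m
    return V_hat, (cov + cov.T) / 2.0


def fit_mrbee(
    panel: HarmonizedPanel,
    ecov: PerVariantErrorCov,
    intercept: bool = False,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
    method_tag: str = "MRBEE",
) -> CausalFit:
    """Fit the bias-corrected estimator in closed form.

    Solves psi(theta) = 0:

        theta_hat = (B'B - sum_j Sigma_wb_wb[j])^-1
                    (B'alpha - sum_j sigma_wb_wa[j]),

    with Jacobian F_hat = m^-1 (B'B - sum_j Sigma_wb_wb[j]), score variance
    V_hat = m^-1 sum_j psi_j psi_j', and covariance m^-1 F^-1 V F^-1. With
    ``intercept`` a constant column with zero measurement error is prepended,
    and the intercept estimates the mean horizontally pleiotropic effect.
    """
    B = panel.exposure_estimates
    alpha = _outcome_vector(panel)
    if ecov.m != panel.m or ecov.p != panel.p:
        raise ShapeError("ecov blocks do not match the panel")
    if ecov.sigma_ba.ndim != 2:
        raise ShapeError("single-outcome fit needs single-outcome blocks")
    names = list(panel.exposure_names)
    if intercept:
        B, ecov = _augment_intercept(B, ecov)
    m, d = B.shape
    if m <= d:
        raise ShapeError(f"need more instruments than coefficients, "
                         f"have m={panel.m} for d={d}")

    theta_full, F_hat = _solve_one(B, alpha, ecov.sigma_bb.sum(axis=0),
                                   ecov.sigma_ba.sum(axis=0), condition_limit)
    psi = score_contributions(theta_full, B, alpha, ecov)
    V_hat, cov = _sandwich(F_hat, psi, m)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, theta_full / se, np.inf * np.sign(theta_full))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CausalFit(
        theta=theta_full[1:] if intercept else theta_full,
        theta0=float(theta_full[0]) if intercept else None,
        covariance=cov, F_hat=F_hat, V_hat=V_hat, m_used=m,
        se=se, p_values=pvals, method_tag=method_tag,
        exposure_names=names, psi=psi,
    )


def fit_ivw(
    panel: HarmonizedPanel,
    intercept: bool = False,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
    method_tag: str = "IVW",
) -> CausalFit:
    """Naive multivariable IVW: the same solver with zero error covariance.

    The least-squares solution with the sandwich covariance machinery; this
    is the biased baseline whose bias the closed forms in
    :mod:`mrbee.diagnostics` predict.
    """
    ecov = PerVariantErrorCov.zero(panel.m, panel.p)
    return fit_mrbee(panel, ecov, intercept=intercept,
                     condition_limit=condition_limit, method_tag=method_tag)


def fit_multivariate(
    panel: HarmonizedPanel,
    ecov: PerVariantErrorCov,
    intercept: bool = False,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> MultiOutcomeFit:
    """Joint fit of q outcomes sharing one instrument set.

    Per-outcome coefficients equal the single-outcome fits; cross-outcome
    covariance blocks are m^-1 F^-1 [m^-1 sum_j psi_j^(a) psi_j^(b)'] F^-1
    from the retained per-variant score contributions, giving the full
    covariance of vec(theta) needed for contrasts across outcomes.
    """
    alpha = np.atleast_2d(panel.outcome_estimates.T).T  # (m, q)
    q = alpha.shape[1]
    if ecov.m != panel.m or ecov.p != panel.p:
        raise ShapeError("ecov blocks do not match the panel")
    ba = ecov.sigma_ba
    aa = ecov.sigma_aa
    if ba.ndim == 2:
        ba, aa = ba[:, :, None], aa[:, None]
    if ba.shape[2] != q or aa.shape[1] != q:
        raise AlignmentError(
            f"covariance blocks cover {ba.shape[2]} outcomes, panel has {q}")

    names = list(panel.exposure_names)
    B = panel.exposure_estimates
    base = PerVariantErrorCov(ecov.sigma_bb, ba[:, :, 0], aa[:, 0])
    if intercept:
        B_aug, _ = _augment_intercept(B, base)
    else:
        B_aug = B
    m, d = B_aug.shape
    if m <= d:
        raise ShapeError(f"need more instruments than coefficients, have m={panel.m}")

    out_ses = np.atleast_2d(panel.outcome_ses.T).T  # (m, q) or (m, 1)
    fits: list[CausalFit] = []
    psis = np.empty((q, m, d))
    for b in range(q):
        sub_panel = HarmonizedPanel(
            variant_ids=panel.variant_ids,
            exposure_estimates=panel.exposure_estimates,
            outcome_estimates=alpha[:, b],
            exposure_ses=panel.exposure_ses,
            outcome_ses=out_ses[:, min(b, out_ses.shape[1] - 1)],
            exposure_names=names,
            standardization=panel.standardization,
        )
        fit = fit_mrbee(sub_panel, PerVariantErrorCov(ecov.sigma_bb, ba[:, :, b], aa[:, b]),
                        intercept=intercept, condition_limit=condition_limit)
        fits.append(fit)
        psis[b] = fit.psi

    F_hat = fits[0].F_hat
    Finv = np.linalg.inv(F_hat)
    Theta = np.empty((d, q))
    for b, fit in enumerate(fits):
        Theta[:, b] = (np.concatenate([[fit.theta0], fit.theta])
                       if intercept else fit.theta)
    cov = np.empty((d * q, d * q))
    for a in range(q):
        for b in range(q):
            Vab = psis[a].T @ psis[b] / m
            block = Finv @ Vab @ Finv / m
            cov[a * d:(a + 1) * d, b * d:(b + 1) * d] = block
    cov = (cov + cov.T) / 2.0
    return MultiOutcomeFit(theta=Theta, covariance=cov, F_hat=F_hat, m_used=m,
                           has_intercept=intercept, method_tag="MRBEE", fits=fits)


def linear_hypothesis_test(
    fit: MultiOutcomeFit | CausalFit,
    spec: HypothesisSpec,
) -> tuple[float, int, float]:
    """Wald test of H0: C' Theta L = mu against chi-square(h*l).

    With H = (L kron C)' the statistic is
    (H vartheta - vec(mu))' (H Lambda H')^-1 (H vartheta - vec(mu)) where
    vartheta = vec(Theta). Covers joint nullity tests, cross-outcome
    contrasts, and mean-difference hypotheses.
    """
    if isinstance(fit, CausalFit):
        d = fit.covariance.shape[0]
        Theta = (np.concatenate([[fit.theta0], fit.theta]) if fit.has_intercept
                 else fit.theta).reshape(d, 1)
        Lambda = fit.covariance
    else:
        Theta, Lambda = fit.theta, fit.covariance
    d, q = Theta.shape
    if spec.C.shape[0] != d:
        raise ShapeError(f"C must have {d} rows (coefficient dimension), got {spec.C.shape[0]}")
    if spec.L.shape[0] != q:
        raise ShapeError(f"L must have {q} rows (outcome dimension), got {spec.L.shape[0]}")
    H = np.kron(spec.L, spec.C).T  # (h*l, d*q)
    delta = H @ Theta.flatten(order="F") - spec.mu.flatten(order="F")
    M = H @ Lambda @ H.T
    M = (M + M.T) / 2.0
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or np.linalg.cond(M) > 1e12:
        raise HypothesisDegeneracyError("H Lambda H' is singular for this hypothesis")
    statistic = float(delta @ np.linalg.solve(M, delta))
    df = spec.C.shape[1] * spec.L.shape[1]
    return statistic, df, float(stats.chi2.sf(statistic, df))
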