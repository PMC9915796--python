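"""Closed-form bias predictors for naive IVW and the concordance diagnostic.

The bias of the naive multivariable IVW estimator factorizes into a
weak-instrument factor (the inverse of the average observed instrument
second moment) and a sample-overlap / measurement-error term:

    bias(theta_IVW) = {Sigma_bb/m + mean_j Sigma_wb_wb[j]}^-1
                      * m^-1 {sum_j sigma_wb_wa[j] - Sigma_wb_wb[j] theta}.

The two terms work in opposite directions: overlap pushes the estimate
toward the error correlation, measurement error attenuates it. With one
exposure and unit phenotypic variances this reduces to

    bias(theta_IVW) = [m / (n1 h2_X + m sigma2_X)]
                      * (n0 sigma_XY / n2 - sigma2_X theta),

see docs/methods.md for the derivation. Comparing predicted bias with the
observed difference between pleiotropy-screened IVW and the bias-corrected
estimate gives a concordance check that differences between the two methods
are explained by the known bias sources rather than by pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CausalFit
from .errorcov import PerVariantErrorCov
from .exceptions import DomainError, InsufficientDataError, SingularCorrectionError
from .io import HarmonizedPanel


@dataclass
class BiasPrediction:
    """Predicted bias of the naive IVW estimate, factorized."""

    bias_vector: np.ndarray  # (p,)
    weak_instrument_factor: np.ndarray  # (p, p) inverted first factor
    overlap_me_term: np.ndarray  # (p,) second factor
    relative_bias: np.ndarray  # (p,) bias / theta * 100 (nan where theta=0)


def predicted_bias_mv(
    theta: np.ndarray,
    panel: HarmonizedPanel,
    ecov: PerVariantErrorCov,
) -> BiasPrediction:
    """Predicted IVW bias with sample plug-ins.

    ``theta`` should be a consistent estimate of the causal effects (e.g.
    the bias-corrected fit). The observed second moment B_hat'B_hat/m
    estimates Sigma_bb/m + mean_j Sigma_wb_wb[j] directly, so it is the
    plug-in for the first factor.
    """
    theta = np.asarray(theta, float)
    B = panel.exposure_estimates
    m = panel.m
    first = B.T @ B / m  # = Sigma_bb/m + mean error covariance, in expectation
    cond = np.linalg.cond(first)
    if not np.isfinite(cond) or cond > 1e10:
        raise SingularCorrectionError("singular instrument second-moment matrix")
    term = (ecov.sigma_ba.sum(axis=0) - ecov.sigma_bb.sum(axis=0) @ theta) / m
    factor = np.linalg.inv(first)
    bias = factor @ term
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(theta != 0, bias / theta * 100.0, np.nan)
    return BiasPrediction(bias, factor, term, rel)


def predicted_bias_uv(
    m: int,
    n1: int,
    n2: int,
    n0: int,
    h2x: float,
    var_x: float = 1.0,
    cov_xy: float = 0.0,
    theta: float = 0.0,
) -> float:
    """Predicted IVW bias for one exposure, in closed form.

    [m / (n1*h2x + m*var_x)] * (n0*cov_xy/n2 - var_x*theta): ``h2x`` is the
    SNP heritability explained by the m instruments, ``var_x`` the exposure
    phenotypic variance, and ``cov_xy`` the exposure-outcome phenotypic
    covariance. Specializes the multivariable formula to p=1.
    """
    if not (0 < h2x <= 1):
        raise DomainError("h2x must be in (0, 1]")
    if n0 > min(n1, n2) or n0 < 0 or min(n1, n2, m) <= 0:
        raise DomainError("need 0 <= n0 <= min(n1, n2) and positive m, n1, n2")
    if var_x <= 0:
        raise DomainError("var_x must be positive")
    return float(m / (n1 * h2x + m * var_x) * (n0 * cov_xy / n2 - var_x * theta))


def bias_concordance(
    fits_star,
    fits_mrbee,
    predictions,
) -> tuple[float, float]:
    """Pearson concordance of predicted and observed IVW* bias.

    Pairs the predicted bias per exposure with the observed difference
    between the screened-IVW and bias-corrected estimates, pooled across
    the given fits (one fit pair per analysis). Returns Pearson r and its
    two-sided p-value for r = 0.
    """
    def coefs(f):
        return np.asarray(f.theta if isinstance(f, CausalFit) else f, float).ravel()

    observed, predicted = [], []
    for fs, fm, pr in zip(fits_star, fits_mrbee, predictions, strict=True):
        observed.append(coefs(fs) - coefs(fm))
        predicted.append(np.asarray(
            pr.bias_vector if isinstance(pr, BiasPrediction) else pr, float).ravel())
    observed = np.concatenate(observed)
    predicted = np.concatenate(predicted)
    if observed.size < 3:
        raise InsufficientDataError("need at least 3 exposure pairs for concordance")
    r, p = stats.pearsonr(predicted, observed)
    return float(r), float(p)
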