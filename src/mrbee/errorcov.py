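"""Correlation structure of GWAS estimation errors across studies.

When exposure and outcome GWAS share participants, the sampling errors of
their per-variant estimates are correlated; together with the error
variances (squared standard errors) this correlation drives every bias
correction in the estimator. The global (p+1)x(p+1) error-correlation matrix
is estimated from jointly non-significant variants — at null variants the
estimate is pure estimation error, so the cross-study correlation of
z-scores is the error correlation — and then expanded to per-variant
covariance blocks using the (fixed) GWAS standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError, ShapeError
from .io import HarmonizedPanel


@dataclass
class ErrorCorrelationMatrix:
    """Global correlation of estimation errors across the p+1 studies.

    Index order follows the panel: exposures first, outcome(s) last.
    """

    matrix: np.ndarray
    n_variants_used: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        k = self.matrix.shape[0]
        if self.matrix.shape != (k, k):
            raise ShapeError("error-correlation matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("error-correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-8):
            raise ValueError("error-correlation matrix must have unit diagonal")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def identity(cls, k: int) -> "ErrorCorrelationMatrix":
        """The no-overlap assumption: independent estimation errors."""
        return cls(np.eye(k))

    def write(self, path, labels: list[str] | None = None) -> None:
        import pandas as pd

        labels = labels or [f"study{i + 1}" for i in range(self.k)]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "ErrorCorrelationMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float))


@dataclass
class PerVariantErrorCov:
    """Per-variant measurement-error covariance blocks.

    ``sigma_bb[j]`` is the p x p error covariance of the j-th variant's
    exposure estimates, ``sigma_ba[j]`` the p-vector (or p x q matrix for q
    outcomes) of exposure-outcome error covariances, and ``sigma_aa[j]`` the
    outcome error variance(s). Standard errors are treated as fixed.
    """

    sigma_bb: np.ndarray  # (m, p, p)
    sigma_ba: np.ndarray  # (m, p) or (m, p, q)
    sigma_aa: np.ndarray  # (m,) or (m, q)

    def __post_init__(self) -> None:
        self.sigma_bb = np.asarray(self.sigma_bb, float)
        self.sigma_ba = np.asarray(self.sigma_ba, float)
        self.sigma_aa = np.asarray(self.sigma_aa, float)
        m, p = self.sigma_bb.shape[:2]
        if self.sigma_bb.shape != (m, p, p):
            raise ShapeError("sigma_bb must be (m, p, p)")
        if self.sigma_ba.shape[0] != m or self.sigma_aa.shape[0] != m:
            raise ShapeError("sigma blocks must share the variant count")
        if self.sigma_ba.shape[1] != p:
            raise ShapeError("sigma_ba must have p rows per variant")

    @property
    def m(self) -> int:
        return self.sigma_bb.shape[0]

    @property
    def p(self) -> int:
        return self.sigma_bb.shape[1]

    @classmethod
    def zero(cls, m: int, p: int, q: int = 1) -> "PerVariantErrorCov":
        """All-zero blocks: no measurement-error correction (plain IVW)."""
        ba = np.zeros((m, p)) if q == 1 else np.zeros((m, p, q))
        aa = np.zeros(m) if q == 1 else np.zeros((m, q))
        return cls(np.zeros((m, p, p)), ba, aa)

    def subset(self, index) -> "PerVariantErrorCov":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PerVariantErrorCov(self.sigma_bb[idx], self.sigma_ba[idx],
                                  self.sigma_aa[idx])

    def outcome_slice(self, q: int) -> "PerVariantErrorCov":
        """Blocks for a single outcome out of a multi-outcome structure."""
        if self.sigma_ba.ndim == 2:
            if q != 0:
                raise ShapeError("single-outcome covariance has only outcome 0")
            return self
        return PerVariantErrorCov(self.sigma_bb, self.sigma_ba[:, :, q],
                                  self.sigma_aa[:, q])


def nearest_psd_correlation(matrix: np.ndarray) -> np.ndarray:
    """Repair a symmetric matrix to a valid correlation matrix.

    Negative eigenvalues are clipped at zero and the result is rescaled to a
    unit diagonal. A valid input passes through unchanged (up to symmetry
    cleanup).
    """
    a = np.asarray(matrix, float)
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    if w.min() >= -1e-12:
        out = a
    else:
        out = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def _truncated_box_correlation(rho: float, c: float, nodes: int = 48) -> float:
    """Correlation of a standard bivariate normal truncated to the box
    [-c, c] x [-c, c], by Gauss-Legendre quadrature."""
    x, w = np.polynomial.legendre.leggauss(nodes)
    x = x * c
    w = w * c
    xx, yy = np.meshgrid(x, x)
    det = 1.0 - rho**2
    dens = np.exp(-(xx**2 - 2 * rho * xx * yy + yy**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det))
    ww = np.outer(w, w)
    mass = np.sum(ww * dens)
    exy = np.sum(ww * dens * xx * yy) / mass
    exx = np.sum(ww * dens * xx**2) / mass
    return float(exy / exx)


def _invert_truncation(r_obs: float, c: float) -> float:
    """Undo the attenuation induced by restricting both z-scores to |z| < c."""
    from scipy.optimize import brentq

    r_obs = float(np.clip(r_obs, -1.0, 1.0))
    if abs(r_obs) < 1e-12 or not np.isfinite(c):
        return r_obs
    lim = _truncated_box_correlation(0.9999, c)
    if abs(r_obs) >= lim:
        return float(np.sign(r_obs))
    return float(brentq(lambda rho: _truncated_box_correlation(rho, c) - r_obs,
                        -0.9999, 0.9999, xtol=1e-8))


def estimate_error_correlation(
    panel: HarmonizedPanel,
    p_cut: float = 0.05,
    min_variants: int = 50,
    selection: str = "pairwise",
) -> ErrorCorrelationMatrix:
    """Estimate the error-correlation matrix from non-significant variants.

    For each study pair, the sample correlation of z-scores is computed over
    variants that are non-significant (two-sided p > ``p_cut``) in the
    relevant studies. Because conditioning each z-score on |z| < z(p_cut)
    truncates the joint normal to a box and attenuates correlations, every
    pairwise estimate is de-attenuated by inverting the
    truncated-bivariate-normal correlation map; the assembled matrix is then
    repaired to the nearest positive semi-definite correlation matrix.

    ``selection="pairwise"`` (default) conditions each pair only on its own
    two studies, which makes the bivariate de-attenuation exact;
    ``"joint"`` uses the single set of variants non-significant in every
    study (one coherent selection, but the bivariate inversion is then only
    approximate when a third correlated study also truncates).

    The panel should be genome-wide (or at least much larger than the IV
    set); the IVs themselves are by construction significant and excluded.
    """
    zx = panel.exposure_estimates / panel.exposure_ses
    zy = np.atleast_2d((panel.outcome_estimates / panel.outcome_ses).T).T
    z = np.hstack([zx, zy])
    nonsig = 2.0 * stats.norm.sf(np.abs(z)) > p_cut
    c = float(stats.norm.isf(p_cut / 2.0))
    k = z.shape[1]
    corr = np.eye(k)
    if selection == "joint":
        mask = nonsig.all(axis=1)
        n_used = int(mask.sum())
        if n_used < min_variants:
            raise InsufficientDataError(
                f"only {n_used} jointly non-significant variants "
                f"(need >= {min_variants})")
        raw = np.corrcoef(z[mask], rowvar=False)
        for a in range(k):
            for b in range(a + 1, k):
                corr[a, b] = corr[b, a] = _invert_truncation(raw[a, b], c)
    elif selection == "pairwise":
        n_used = z.shape[0]
        for a in range(k):
            for b in range(a + 1, k):
                mask = nonsig[:, a] & nonsig[:, b]
                n_pair = int(mask.sum())
                n_used = min(n_used, n_pair)
                if n_pair < min_variants:
                    raise InsufficientDataError(
                        f"only {n_pair} non-significant variants for studies "
                        f"({a}, {b}) (need >= {min_variants})")
                raw = float(np.corrcoef(z[mask][:, [a, b]], rowvar=False)[0, 1])
                corr[a, b] = corr[b, a] = _invert_truncation(raw, c)
    else:
        raise ValueError("selection must be 'pairwise' or 'joint'")
    return ErrorCorrelationMatrix(nearest_psd_correlation(corr), n_used)


def expand_to_covariances(
    corr: ErrorCorrelationMatrix,
    panel: HarmonizedPanel,
) -> PerVariantErrorCov:
    """Convert the global error correlation to per-variant covariance blocks.

    For variant j and studies k, l the covariance is
    ``corr[k, l] * se_jk * se_jl``; standard errors are treated as fixed
    constants. The correlation matrix indexes exposures first, outcome(s)
    last, matching the panel.
    """
    p = panel.p
    q = panel.n_outcomes
    if corr.k != p + q:
        raise ShapeError(f"correlation matrix is {corr.k}x{corr.k}, panel needs {p + q}")
    se_x = panel.exposure_ses  # (m, p)
    se_y = np.atleast_2d(panel.outcome_ses.T).T  # (m, q)
    se = np.hstack([se_x, se_y])  # (m, p+q)
    # full (m, p+q, p+q) covariance, then partition
    full = corr.matrix[None, :, :] * se[:, :, None] * se[:, None, :]
    sigma_bb = full[:, :p, :p]
    sigma_ba = full[:, :p, p:]
    sigma_aa = full[:, p:, p:][:, np.arange(q), np.arange(q)]
    if q == 1:
        sigma_ba = sigma_ba[:, :, 0]
        sigma_aa = sigma_aa[:, 0]
    return PerVariantErrorCov(sigma_bb, sigma_ba, sigma_aa)


def theoretical_overlap_correlation(n1: int, n2: int, n0: int, rho: float) -> float:
    """Error correlation induced by sample overlap.

    Two GWAS with sample sizes ``n1`` and ``n2`` sharing ``n0`` participants
    on phenotypes correlated at ``rho`` have estimation-error correlation
    n0*rho/sqrt(n1*n2) (clipped to [-1, 1]).
    """
    if n1 <= 0 or n2 <= 0 or n0 < 0:
        raise DomainError("sample sizes must be positive and overlap non-negative")
    if n0 > min(n1, n2):
        raise DomainError(f"overlap n0={n0} exceeds min(n1, n2)={min(n1, n2)}")
    if abs(rho) > 1:
        raise DomainError(f"|rho| must be <= 1, got {rho}")
    return float(np.clip(n0 * rho / np.sqrt(n1 * n2), -1.0, 1.0))
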