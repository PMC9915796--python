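"""Score functions, closed-form fits, sandwich covariance, Wald tests."""

import numpy as np
import pytest
from scipy import optimize

from mrbee import (
    HarmonizedPanel,
    HypothesisSpec,
    PerVariantErrorCov,
    SimulationConfig,
    fit_ivw,
    fit_mrbee,
    fit_multivariate,
    ivw_score,
    linear_hypothesis_test,
    mrbee_score,
    simulate_study,
)
from mrbee.core import score_contributions
from mrbee.exceptions import (
    HypothesisDegeneracyError,
    ShapeError,
    SingularCorrectionError,
)


def panel_from_arrays(B, alpha, ses=None):
    B = np.atleast_2d(np.asarray(B, float).T).T
    m, p = B.shape
    ses = np.full((m, p + 1), 0.01) if ses is None else ses
    return HarmonizedPanel(
        variant_ids=[f"rs{i}" for i in range(m)],
        exposure_estimates=B, outcome_estimates=np.asarray(alpha, float),
        exposure_ses=ses[:, :p], outcome_ses=ses[:, p],
        exposure_names=[f"x{k}" for k in range(p)])


class TestScores:
    def test_ivw_score_zero_at_least_squares(self, rng):
        B = rng.standard_normal((20, 3))
        alpha = rng.standard_normal(20)
        theta_ls = np.linalg.lstsq(B, alpha, rcond=None)[0]
        np.testing.assert_allclose(ivw_score(theta_ls, panel_from_arrays(B, alpha)),
                                   0.0, atol=1e-10)

    def test_ivw_score_hand_example(self):
        # p=1, beta=(1,1), alpha=(1,1), theta=0 -> sum beta*(alpha-beta*theta) = 2
        panel = panel_from_arrays([1.0, 1.0], [1.0, 1.0])
        assert ivw_score(np.array([0.0]), panel)[0] == pytest.approx(2.0)

    def test_ivw_score_linearity(self, rng):
        B = rng.standard_normal((15, 2))
        panel = panel_from_arrays(B, rng.standard_normal(15))
        theta = rng.standard_normal(2)
        delta = rng.standard_normal(2)
        diff = ivw_score(theta + delta, panel) - ivw_score(theta, panel)
        np.testing.assert_allclose(diff, -B.T @ B @ delta, rtol=1e-10)

    def test_mrbee_score_degenerates_to_ivw(self, rng):
        B = rng.standard_normal((10, 2))
        alpha = rng.standard_normal(10)
        panel = panel_from_arrays(B, alpha)
        theta = rng.standard_normal(2)
        np.testing.assert_array_equal(
            mrbee_score(theta, panel, PerVariantErrorCov.zero(10, 2)),
            ivw_score(theta, panel))

    def test_mrbee_score_hand_example(self):
        # beta=0.1, alpha=0.05, Sigma_wb=0.001, sigma_wbwa=0, theta=0.5
        panel = panel_from_arrays([0.1], [0.05])
        ecov = PerVariantErrorCov([[[0.001]]], [[0.0]], [0.0001])
        s = mrbee_score(np.array([0.5]), panel, ecov)
        assert s[0] == pytest.approx(5e-4)

    def test_score_unbiased_at_truth(self):
        """Mean per-variant score contribution at the generating value ~ 0."""
        cfg = SimulationConfig(m=4000, p=2, theta_true=[0.5, 0.5], seed=17)
        study = simulate_study(cfg)
        psi = score_contributions(cfg.theta_true, study.panel.exposure_estimates,
                                  study.panel.outcome_estimates, study.ecov_true)
        mc_se = psi.std(axis=0) / np.sqrt(cfg.m)
        assert (np.abs(psi.mean(axis=0)) < 3 * mc_se).all()

    def test_block_count_mismatch(self, rng):
        panel = panel_from_arrays(rng.standard_normal((10, 1)), rng.standard_normal(10))
        with pytest.raises(ShapeError):
            mrbee_score(np.zeros(1), panel, PerVariantErrorCov.zero(9, 1))


class TestFitMrbee:
    def test_zero_ecov_equals_ivw_exactly(self, null_study):
        panel = null_study.panel
        fit_a = fit_mrbee(panel, PerVariantErrorCov.zero(panel.m, panel.p))
        fit_b = fit_ivw(panel)
        np.testing.assert_array_equal(fit_a.theta, fit_b.theta)
        np.testing.assert_array_equal(fit_a.covariance, fit_b.covariance)

    def test_hand_example(self):
        # theta = (B'a - 0)/(B'B - 3*0.001) = 0.07/0.137
        panel = panel_from_arrays([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        ecov = PerVariantErrorCov(np.full((3, 1, 1), 0.001), np.zeros((3, 1)),
                                  np.full(3, 1e-4))
        fit = fit_mrbee(panel, ecov)
        assert fit.theta[0] == pytest.approx(0.07 / 0.137)

    @pytest.mark.parametrize("p", [1, 2])
    def test_closed_form_matches_root_finding(self, p, rng):
        """Numeric root of the corrected score equals the closed form."""
        m = 15
        cfg = SimulationConfig(m=m, p=p, theta_true=[0.4] * p, seed=int(rng.integers(1e6)))
        study = simulate_study(cfg)
        fit = fit_mrbee(study.panel, study.ecov_true)
        root = optimize.root(
            lambda t: mrbee_score(t, study.panel, study.ecov_true),
            x0=np.zeros(p), method="lm", tol=1e-14)
        np.testing.assert_allclose(
            mrbee_score(root.x, study.panel, study.ecov_true), 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.theta, root.x, atol=1e-8)

    def test_exact_fit_ivw(self):
        panel = panel_from_arrays([1.0, 2.0], [2.0, 4.0])
        assert fit_ivw(panel).theta[0] == pytest.approx(2.0)

    def test_singular_correction_guard(self):
        panel = panel_from_arrays([0.01, 0.02, 0.03], [0.005, 0.01, 0.015])
        # correction exactly cancels the observed second moment
        bb = np.sum(np.square([0.01, 0.02, 0.03])) / 3
        ecov = PerVariantErrorCov(np.full((3, 1, 1), bb), np.zeros((3, 1)),
                                  np.full(3, 1e-4))
        with pytest.raises(SingularCorrectionError, match="condition"):
            fit_mrbee(panel, ecov)

    def test_intercept_recovers_constant_shift(self, uni_study):
        panel = uni_study.panel.subset(np.arange(uni_study.panel.m))
        panel.outcome_estimates = panel.outcome_estimates + 0.05
        fit = fit_mrbee(panel, uni_study.ecov_true, intercept=True)
        assert fit.theta0 == pytest.approx(0.05, abs=3 * fit.theta0_se)
        assert fit.covariance.shape == (2, 2)

    def test_se_are_covariance_roots(self, null_study):
        fit = fit_mrbee(null_study.panel, null_study.ecov_true)
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(fit.covariance)))


class TestFitMultivariate:
    @staticmethod
    def two_outcome_study(seed, outcome_err_corr, thetas=(0.5, 0.2)):
        """One exposure, two outcomes whose estimation errors correlate."""
        rng = np.random.default_rng(seed)
        m, n = 300, 20_000
        beta = rng.normal(0, np.sqrt(0.3 / m), m)
        se = 1 / np.sqrt(n)
        corr = np.eye(3)
        corr[1, 2] = corr[2, 1] = outcome_err_corr
        L = np.linalg.cholesky(corr) * se
        W = rng.standard_normal((m, 3)) @ L.T
        alpha = np.column_stack([beta * thetas[0], beta * thetas[1]]) + W[:, 1:]
        panel = HarmonizedPanel(
            variant_ids=[f"rs{i}" for i in range(m)],
            exposure_estimates=beta[:, None] + W[:, :1],
            outcome_estimates=alpha,
            exposure_ses=np.full((m, 1), se), outcome_ses=np.full((m, 2), se),
            exposure_names=["x"])
        ecov = PerVariantErrorCov(
            np.full((m, 1, 1), se**2), np.zeros((m, 1, 2)), np.full((m, 2), se**2))
        return panel, ecov

    def test_single_outcome_degenerate_case(self, uni_study):
        mf = fit_multivariate(uni_study.panel, uni_study.ecov_true)
        sf = fit_mrbee(uni_study.panel, uni_study.ecov_true)
        np.testing.assert_array_equal(mf.theta[:, 0], sf.theta)
        np.testing.assert_allclose(mf.covariance, sf.covariance)

    def test_independent_outcomes_near_zero_cross_block(self):
        # at zero causal effects the shared exposure errors do not couple
        # the two outcome scores, so the cross-block is pure noise
        panel, ecov = self.two_outcome_study(5, 0.0, thetas=(0.0, 0.0))
        mf = fit_multivariate(panel, ecov)
        cross = mf.covariance[0, 1]
        scale = np.sqrt(mf.covariance[0, 0] * mf.covariance[1, 1])
        assert abs(cross) < 0.25 * scale

    def test_cross_block_predicts_estimate_correlation(self):
        """Monte-Carlo correlation of the two outcome estimates matches the
        cross-covariance block prediction."""
        R = 200
        est = np.empty((R, 2))
        pred = []
        for r in range(R):
            panel, ecov = self.two_outcome_study(1000 + r, 0.8)
            mf = fit_multivariate(panel, ecov)
            est[r] = mf.theta[0]
            pred.append(mf.covariance[0, 1]
                        / np.sqrt(mf.covariance[0, 0] * mf.covariance[1, 1]))
        emp = np.corrcoef(est.T)[0, 1]
        assert emp == pytest.approx(np.mean(pred), abs=0.12)


class TestLinearHypothesis:
    def test_single_coefficient_is_squared_z(self, null_study):
        mf = fit_multivariate(null_study.panel, null_study.ecov_true)
        spec = HypothesisSpec(C=[[1.0], [0.0]], L=[[1.0]], mu=[[0.0]])
        stat, df, p = linear_hypothesis_test(mf, spec)
        z2 = (mf.theta[0, 0] ** 2) / mf.covariance[0, 0]
        assert df == 1
        assert stat == pytest.approx(z2, rel=1e-10)

    def test_df_is_h_times_l(self):
        panel, ecov = TestFitMultivariate.two_outcome_study(11, 0.5)
        panel.exposure_estimates = np.column_stack(
            [panel.exposure_estimates[:, 0],
             np.random.default_rng(0).normal(0, 0.03, panel.m)])
        panel.exposure_ses = np.hstack([panel.exposure_ses, panel.exposure_ses])
        panel.exposure_names = ["x1", "x2"]
        ecov2 = PerVariantErrorCov(
            np.tile(np.eye(2) * ecov.sigma_bb[0, 0, 0], (panel.m, 1, 1)),
            np.zeros((panel.m, 2, 2)), ecov.sigma_aa)
        mf = fit_multivariate(panel, ecov2)
        spec = HypothesisSpec(C=np.eye(2), L=np.eye(2), mu=np.zeros((2, 2)))
        _, df, _ = linear_hypothesis_test(mf, spec)
        assert df == 4

    def test_hand_computed_quadratic_form(self):
        from mrbee.core import CausalFit, MultiOutcomeFit

        theta = np.array([[0.3], [0.1]])
        Lam = np.array([[0.04, 0.01], [0.01, 0.02]])
        mf = MultiOutcomeFit(theta=theta.reshape(2, 1), covariance=Lam,
                             F_hat=np.eye(2), m_used=10, has_intercept=False,
                             method_tag="MRBEE")
        # equality contrast x1 - x2 = 0
        spec = HypothesisSpec(C=[[1.0], [-1.0]], L=[[1.0]], mu=[[0.0]])
        stat, df, _ = linear_hypothesis_test(mf, spec)
        c = np.array([1.0, -1.0])
        expected = (c @ theta[:, 0]) ** 2 / (c @ Lam @ c)
        assert stat == pytest.approx(expected, rel=1e-12)
        assert df == 1

    def test_degenerate_hypothesis(self, null_study):
        mf = fit_multivariate(null_study.panel, null_study.ecov_true)
        # duplicated contrast rows make H Lambda H' singular
        spec = HypothesisSpec(C=[[1.0, 1.0], [0.0, 0.0]], L=[[1.0]],
                              mu=np.zeros((2, 1)))
        with pytest.raises(HypothesisDegeneracyError):
            linear_hypothesis_test(mf, spec)
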