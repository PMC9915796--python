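"""S_pleio, Q_pleio, iterative outlier removal, BH, and locus classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrbee import (
    AlgorithmSettings,
    LocusCall,
    PerVariantErrorCov,
    SimulationConfig,
    benjamini_hochberg,
    classify_loci,
    fit_ivw,
    fit_ivw_star,
    fit_mrbee,
    genome_scan,
    imrp_loop,
    qpleio,
    simulate_study,
    spleio,
)
from mrbee.core import CausalFit
from mrbee.exceptions import ClassificationError, OverPruningError
from mrbee.pleiotropy import bh_qvalues


class TestBenjaminiHochberg:
    def test_hand_stepup(self):
        # m=4, level 0.05: thresholds 0.0125, 0.025, 0.0375, 0.05
        flags = benjamini_hochberg(np.array([0.001, 0.01, 0.2, 0.9]), 0.05)
        np.testing.assert_array_equal(flags, [True, True, False, False])

    def test_all_ones_flag_none(self):
        assert not benjamini_hochberg(np.ones(10), 0.5).any()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60)) ** rng.uniform(1, 4)
            flags = benjamini_hochberg(p, 0.05)
            ref_flags, ref_q, *_ = multipletests(p, 0.05, method="fdr_bh")
            np.testing.assert_array_equal(flags, ref_flags)
            np.testing.assert_allclose(bh_qvalues(p), ref_q, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms())
    @settings(max_examples=30, deadline=None)
    def test_order_invariance(self, pvals, pyrandom):
        p = np.array(pvals)
        perm = np.arange(p.size)
        pyrandom.shuffle(perm)
        flags = benjamini_hochberg(p, 0.05)
        flags_perm = benjamini_hochberg(p[perm], 0.05)
        np.testing.assert_array_equal(flags[perm], flags_perm)


class TestSpleio:
    def test_zero_residual_gives_zero_statistic(self, uni_study):
        panel = uni_study.panel.subset(np.arange(uni_study.panel.m))
        fit = fit_mrbee(panel, uni_study.ecov_true)
        panel.outcome_estimates = panel.outcome_estimates.copy()
        panel.outcome_estimates[0] = panel.exposure_estimates[0] @ fit.theta
        res = spleio(panel, fit, uni_study.ecov_true)
        assert res.s_pleio[0] == 0.0
        assert res.p_values[0] == 1.0

    def test_hand_example(self):
        # residual 0.02 with variance 1e-4 -> S = 4, p = P(chi2(1) > 4)
        from mrbee import HarmonizedPanel

        panel = HarmonizedPanel(
            variant_ids=["rs1"], exposure_estimates=[[0.0]],
            outcome_estimates=[0.02], exposure_ses=[[0.01]], outcome_ses=[0.01],
            exposure_names=["x"])
        fit = CausalFit(theta=np.zeros(1), theta0=None, covariance=np.zeros((1, 1)),
                        F_hat=np.eye(1), V_hat=np.eye(1), m_used=1,
                        se=np.zeros(1), p_values=np.ones(1), method_tag="MRBEE")
        ecov = PerVariantErrorCov(np.zeros((1, 1, 1)), np.zeros((1, 1)), [1e-4])
        res = spleio(panel, fit, ecov)
        assert res.s_pleio[0] == pytest.approx(4.0)
        assert res.p_values[0] == pytest.approx(0.0455, abs=2e-4)

    def test_null_distribution_is_chi2_1(self):
        """Goodness of fit of S_pleio to chi-square(1) under no pleiotropy."""
        study = simulate_study(SimulationConfig(m=5000, p=1, seed=42))
        fit = fit_mrbee(study.panel, study.ecov_true)
        res = spleio(study.panel, fit, study.ecov_true)
        ks = stats.kstest(res.s_pleio, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_type_one_calibration(self):
        study = simulate_study(SimulationConfig(m=5000, p=1, seed=42))
        fit = fit_mrbee(study.panel, study.ecov_true)
        res = spleio(study.panel, fit, study.ecov_true)
        frac = np.mean(res.p_values < 0.05)
        assert frac == pytest.approx(0.05, abs=2 * np.sqrt(0.05 * 0.95 / 5000))

    def test_sign_flip_invariance(self, uni_study):
        fit = fit_mrbee(uni_study.panel, uni_study.ecov_true)
        res_a = spleio(uni_study.panel, fit, uni_study.ecov_true)
        flipped = uni_study.panel.subset(np.arange(uni_study.panel.m))
        flipped.exposure_estimates = flipped.exposure_estimates.copy()
        flipped.outcome_estimates = flipped.outcome_estimates.copy()
        flipped.exposure_estimates[3] *= -1
        flipped.outcome_estimates[3] *= -1
        res_b = spleio(flipped, fit, uni_study.ecov_true)
        assert res_b.s_pleio[3] == pytest.approx(res_a.s_pleio[3], rel=1e-12)


class TestQpleio:
    def test_null_rejection_near_nominal(self):
        """Symmetric mean-zero pleiotropy: Q_pleio rejects at ~ the level."""
        rejected = 0
        R = 60
        for r in range(R):
            cfg = SimulationConfig(m=300, p=1, uhp_fraction=0.2, seed=900 + r)
            study = simulate_study(cfg)
            if qpleio(study.panel, study.ecov_true).p_value < 0.05:
                rejected += 1
        assert rejected / R < 0.05 + 3 * np.sqrt(0.05 * 0.95 / R)

    def test_constant_shift_recovered(self, uni_study):
        panel = uni_study.panel.subset(np.arange(uni_study.panel.m))
        panel.outcome_estimates = panel.outcome_estimates + 0.03
        q = qpleio(panel, uni_study.ecov_true)
        assert q.fit.theta0 == pytest.approx(0.03, abs=3 * q.fit.theta0_se)
        # statistic referred to chi2(1)
        assert q.p_value == pytest.approx(stats.chi2.sf(q.statistic, 1))
        assert q.p_value < 1e-6

    def test_grows_with_m(self):
        stats_by_m = []
        for m in (200, 800):
            study = simulate_study(SimulationConfig(m=m, p=1, seed=77))
            panel = study.panel.subset(np.arange(m))
            panel.outcome_estimates = panel.outcome_estimates + 0.03
            stats_by_m.append(qpleio(panel, study.ecov_true).statistic)
        assert stats_by_m[1] > stats_by_m[0]


def plant_outliers(study, fraction=0.10, variance=None, seed=0):
    """Plant large tail-restricted pleiotropic effects on a random subset."""
    rng = np.random.default_rng(seed)
    m = study.panel.m
    variance = 16.0 / m if variance is None else variance
    idx = rng.choice(m, size=int(round(fraction * m)), replace=False)
    z = stats.norm.ppf(rng.uniform(0, 0.05, idx.size))
    gamma = np.sqrt(variance) * np.abs(z) * rng.choice([-1, 1], idx.size)
    panel = study.panel.subset(np.arange(m))
    panel.outcome_estimates = panel.outcome_estimates.copy()
    panel.outcome_estimates[idx] += gamma
    return panel, idx


class TestImrpLoop:
    def test_clean_data_no_removals(self, uni_study):
        res = imrp_loop(uni_study.panel, uni_study.ecov_true)
        assert res.removed == []
        assert res.n_iterations <= 2
        assert res.converged

    def test_planted_outliers_recovered(self):
        """>= 80% of planted tail outliers are removed, on average."""
        hits, planted = 0, 0
        for r in range(5):
            study = simulate_study(SimulationConfig(m=500, p=1, seed=50 + r))
            panel, idx = plant_outliers(study, 0.10, seed=150 + r)
            res = imrp_loop(panel, study.ecov_true)
            removed = set(res.removed)
            hits += sum(panel.variant_ids[i] in removed for i in idx)
            planted += idx.size
        assert hits / planted >= 0.80

    def test_estimate_recovered_after_removal(self):
        study = simulate_study(SimulationConfig(m=1000, p=1, seed=60))
        panel, _ = plant_outliers(study, 0.10, seed=61)
        res = imrp_loop(panel, study.ecov_true)
        assert res.fit.theta[0] == pytest.approx(0.5, abs=4 * res.fit.se[-1])

    def test_fixed_point_on_own_output(self):
        study = simulate_study(SimulationConfig(m=500, p=1, seed=62))
        panel, _ = plant_outliers(study, 0.10, seed=63)
        res = imrp_loop(panel, study.ecov_true)
        keep = [i for i, v in enumerate(panel.variant_ids) if v not in set(res.removed)]
        res2 = imrp_loop(panel.subset(keep), study.ecov_true.subset(keep))
        assert res2.removed == []

    def test_over_pruning_error(self):
        study = simulate_study(SimulationConfig(m=8, p=1, h2_exposure=0.5, seed=3))
        panel = study.panel.subset(np.arange(8))
        panel.outcome_estimates = panel.outcome_estimates + np.linspace(1, 8, 8)
        with pytest.raises(OverPruningError):
            imrp_loop(panel, study.ecov_true, AlgorithmSettings(xi=0.5))


class TestIvwStar:
    def test_no_flags_equals_full_ivw(self, uni_study):
        star = fit_ivw_star(uni_study.panel, uni_study.ecov_true)
        plain = fit_ivw(uni_study.panel)
        assert star.method_tag == "IVW_star"
        np.testing.assert_array_equal(star.theta, plain.theta)

    def test_removes_planted_outliers(self):
        study = simulate_study(SimulationConfig(m=500, p=1, seed=70))
        panel, idx = plant_outliers(study, 0.10, seed=71)
        star = fit_ivw_star(panel, study.ecov_true)
        assert star.m_used < panel.m


class TestClassifyLoci:
    def make(self, g, s, e):
        return LocusCall("rs1", g, s, e)

    @pytest.mark.parametrize("g,s,e,expected", [
        (1e-10, 0.4, 1e-10, "mediation"),
        (1e-10, 1e-10, 0.5, "direct"),
        (1e-10, 1e-10, 1e-10, "pleiotropy"),
        (9.3e-3, 3.5e-8, 0.5, "novel"),
    ])
    def test_rule(self, g, s, e, expected):
        assert classify_loci([self.make(g, s, e)])[0].category == expected

    def test_missing_pvalue(self):
        with pytest.raises(ClassificationError, match="exposure_p"):
            classify_loci([self.make(1e-10, 0.4, np.nan)])

    def test_generative_recovery(self):
        """Loci generated under the four causal diagrams are recovered."""
        rng = np.random.default_rng(8)
        theta, n, reps = 0.5, 500_000, 40
        se = 1 / np.sqrt(n)
        correct = total = 0
        for kind in ("mediation", "direct", "pleiotropy", "novel"):
            for _ in range(reps):
                if kind == "mediation":
                    b, g = 0.05, 0.0
                elif kind == "direct":
                    b, g = 0.0, 0.05
                elif kind == "pleiotropy":
                    b, g = 0.05, 0.05
                else:  # novel: outcome association cancels, residual does not
                    b, g = 0.05, -0.05 * theta
                alpha = b * theta + g
                bh = b + rng.normal(0, se)
                ah = alpha + rng.normal(0, se)
                gwas_p = 2 * stats.norm.sf(abs(ah) / se)
                resid = ah - bh * theta
                ups = se**2 + theta**2 * se**2
                spl_p = stats.chi2.sf(resid**2 / ups, 1)
                exp_p = stats.chi2.sf((bh / se) ** 2, 1)
                try:
                    got = classify_loci([LocusCall("rs", gwas_p, spl_p, exp_p)])[0]
                    correct += got.category == kind
                except ClassificationError:
                    pass
                total += 1
        assert correct / total >= 0.90


class TestGenomeScan:
    def test_consistent_panel_yields_no_loci(self):
        study = simulate_study(SimulationConfig(m=400, p=1, theta_true=0.0, seed=81))
        fit = fit_mrbee(study.panel, study.ecov_true)
        loci = genome_scan(study.panel, fit, study.ecov_true)
        assert loci == []

    def test_planted_direct_locus_found(self):
        study = simulate_study(SimulationConfig(m=400, p=1, theta_true=0.0, seed=80))
        fit = fit_mrbee(study.panel, study.ecov_true)
        panel = study.panel.subset(np.arange(400))
        panel.exposure_estimates = panel.exposure_estimates.copy()
        panel.outcome_estimates = panel.outcome_estimates.copy()
        panel.exposure_estimates[100] = 0.0  # no exposure pathway
        panel.outcome_estimates[100] = 0.2  # strong direct outcome effect
        panel.outcome_pvalues = None
        panel.exposure_pvalues = None
        loci = genome_scan(panel, fit, study.ecov_true)
        assert len(loci) == 1
        assert loci[0].lead_variant == panel.variant_ids[100]
        assert loci[0].category == "direct"
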