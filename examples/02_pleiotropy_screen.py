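"""Detect and remove horizontally pleiotropic instruments.

Plants outlier-like pleiotropic effects on 10% of instruments, shows that
the global intercept test (Q_pleio) and per-variant test (S_pleio) detect
them, and that the iterative fit-test-remove loop restores an unbiased
causal estimate.
"""

import numpy as np

from mrbee import SimulationConfig, fit_mrbee, imrp_loop, qpleio, simulate_study, spleio

config = SimulationConfig(m=1000, p=1, theta_true=0.5, uhp_fraction=0.10,
                          uhp_variance=16 / 1000, outlier_tails=True, seed=4)
study = simulate_study(config)
planted = set(np.flatnonzero(study.true_gamma != 0))

naive = fit_mrbee(study.panel, study.ecov_true)
q = qpleio(study.panel, study.ecov_true)
print(f"fit on all IVs:      theta = {naive.theta[0]:.4f} (truth 0.5)")
print(f"Q_pleio = {q.statistic:.1f}, p = {q.p_value:.2e}  "
      "(tests *unbalanced* pleiotropy: symmetric outliers keep it null,")
print("                     so per-IV screening with S_pleio is still needed)")

scan = spleio(study.panel, naive, study.ecov_true)
flagged = set(np.flatnonzero(scan.flagged))
print(f"S_pleio flags {len(flagged)} IVs (BH 5%); "
      f"{len(flagged & planted)} of {len(planted)} planted outliers among them")

loop = imrp_loop(study.panel, study.ecov_true)
print(f"after IMRP loop:     theta = {loop.fit.theta[0]:.4f} "
      f"({len(loop.removed)} IVs removed in {loop.n_iterations} iterations)")
# The post-removal estimate should be within ~2 SEs of 0.5.
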