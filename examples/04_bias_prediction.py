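"""Predict naive-IVW bias in closed form and check it against simulation.

The bias of naive IVW factorizes into a weak-instrument factor and an
overlap/measurement-error term; both are computable from sample sizes,
overlap, heritability, and the (estimated) causal effect. This script
evaluates the univariable closed form on a grid of overlap fractions and
compares with the empirical IVW bias, then shows the concordance
diagnostic across several multi-exposure studies.
"""

import numpy as np

from mrbee import (
    SimulationConfig, bias_concordance, fit_ivw_star, fit_mrbee,
    predicted_bias_mv, predicted_bias_uv, run_experiment, simulate_study,
)

n, m = 20_000, 1000
print("overlap  predicted_bias  empirical_bias (IVW, theta=0.5)")
for frac in (0.0, 0.5, 1.0):
    pred = predicted_bias_uv(m, n, n, int(frac * n), h2x=0.3, var_x=1.0,
                             cov_xy=0.5, theta=0.5)
    cfg = SimulationConfig(m=m, n_overlap=int(frac * n), theta_true=0.5, seed=6)
    emp = run_experiment(cfg, ("IVW",), replicates=60, seed=6).summary.iloc[0]
    print(f"  {frac:3.1f}    {pred:+.4f}         {emp['mean_bias']:+.4f}")

fits_star, fits_bee, preds = [], [], []
for i, overlap in enumerate((1.0, 0.5, 0.0, 1.0)):
    cfg = SimulationConfig(m=m, p=3, h2_exposure=[0.3, 0.2, 0.1],
                           theta_true=[0.5, 0.3, 0.1] if i % 2 else [0.0, 0.2, 0.4],
                           n_overlap=int(overlap * n), seed=10 + i)
    study = simulate_study(cfg)
    bee = fit_mrbee(study.panel, study.ecov_true)
    fits_bee.append(bee)
    fits_star.append(fit_ivw_star(study.panel, study.ecov_true))
    preds.append(predicted_bias_mv(bee.theta, study.panel, study.ecov_true))
r, p = bias_concordance(fits_star, fits_bee, preds)
print(f"\nconcordance of predicted bias with observed IVW*-MRBEE differences:")
print(f"Pearson r = {r:.3f} (p = {p:.2e}) across "
      f"{sum(f.p for f in fits_bee)} exposure estimates")
# r near 1 indicates the method differences are explained by the known
# bias sources, not by residual pleiotropy.
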