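"""Fit bias-corrected causal effects on a small synthetic two-exposure study.

Simulates GWAS summary statistics for two genetically correlated exposures
and one outcome with fully overlapping samples, then fits the naive IVW
estimator and the bias-corrected estimator with the true error covariances.
"""

import numpy as np

from mrbee import SimulationConfig, fit_ivw, fit_mrbee, simulate_study

config = SimulationConfig(
    m=1000, p=2, n_exposure=20_000, n_outcome=20_000,
    h2_exposure=[0.3, 0.3], genetic_corr=0.5, pheno_corr=0.5,
    theta_true=[0.5, 0.2], seed=1,
)
study = simulate_study(config)

ivw = fit_ivw(study.panel)
bee = fit_mrbee(study.panel, study.ecov_true)

print("true direct effects:", config.theta_true)
print("\nnaive IVW:")
print(ivw.summary().to_string(index=False))
print("\nbias-corrected (MRBEE):")
print(bee.summary().to_string(index=False))
print("\nIVW error vs truth:   ", np.round(ivw.theta - config.theta_true, 4))
print("corrected error:      ", np.round(bee.theta - config.theta_true, 4))

# The corrected estimates should sit within ~2 sandwich SEs of the truth,
# while naive IVW is systematically pulled by weak-instrument/overlap bias.
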