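"""Replicate experiment: bias, coverage, and false positives by estimator.

Reproduces the two headline simulation findings at reduced replicate count:
(1) at the reference settings the corrected estimator is unbiased with
nominal 95% coverage; (2) with full sample overlap and no causal effect,
naive IVW rejects the true null essentially always.
"""

from mrbee import SimulationConfig, run_experiment

print("reference settings (theta = 0.5, full overlap, no pleiotropy):")
cfg = SimulationConfig(m=1000, p=1, theta_true=0.5, seed=2)
res = run_experiment(cfg, ("MRBEE", "IVW"), replicates=100, seed=2)
cols = ["estimator", "mean_estimate", "mean_bias", "empirical_sd", "mean_se",
        "coverage", "rejection_rate"]
print(res.summary[cols].round(4).to_string(index=False))

print("\nnull effect, n=30k, full overlap (false-positive stress test):")
cfg0 = SimulationConfig(m=1000, p=1, n_exposure=30_000, n_outcome=30_000,
                        theta_true=0.0, seed=3)
res0 = run_experiment(cfg0, ("MRBEE", "IVW"), replicates=100, seed=3)
print(res0.summary[cols].round(4).to_string(index=False))
# 'rejection_rate' in the null experiment is the false-positive rate at
# nominal 0.05: ~1.0 for naive IVW, ~0.05 for the corrected estimator.
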