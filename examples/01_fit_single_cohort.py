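"""Fit growth autocorrelation to one simulated cohort of unmarked animals.

Simulates a cohort of 200 individuals measured on 16 occasions with true
autocorrelation rho^2 = 0.49 (70% of growth-rate SD permanent), then
estimates rho from nothing but the per-occasion size variances.
"""

import numpy as np

from growthcorr import GrowthParams, fit, simulate_cohort, test_rho_positive

params = GrowthParams(rho=0.7, sigma2=16.0, n_t=16)
cohort = simulate_cohort(params, n_individuals=200, seed=42)

traj = cohort.variance_trajectory()
print("occasion variances:", np.round(traj.variances, 2))

result = fit(traj)
print(f"rho_hat    = {result.rho_hat:.3f}   (true 0.700)")
print(f"rho^2_hat  = {result.rho2_hat:.3f}   (true 0.490)")
print(f"sigma^2    = {result.sigma2_hat:.2f}    (true 16)")
print(f"95% CI rho = ({result.rho_ci[0]:.3f}, {result.rho_ci[1]:.3f})")
print("reject rho=0:", test_rho_positive(result))
# The CI excluding zero means the increase in size variance is too
# front-loaded-linear/late-quadratic to be explained by uncorrelated
# step-to-step growth noise alone.
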