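"""Corrected correlations are invariant to trial noise; sample correlations shrink.

Simulates a one-factorial design (3 stimuli, 5 trials each, 100 voxels)
whose hidden pattern components have correlations (0, -0.2, 0.8), fits the
unconstrained pattern-component model by EM, and compares the corrected
correlation rho23 = gamma23/(sigma2 sigma3) against the plain sample
correlation between condition-mean patterns at several noise levels.
"""

import numpy as np

from pcmodel import RunConfig, expected_sample_corr, run_scenario_grid

_, summary = run_scenario_grid(
    RunConfig(scenario="one_factorial", replicates=100, seed=0)
)

print("noise   corrected rho23   sample rho23   analytic sample rho23")
for nv in (0.5, 2.0, 5.0, 10.0):
    row = summary[(summary.noise_var == nv) & (summary.name == "rho23")]
    corrected = row[row.estimator == "corrected"]["mean"].iloc[0]
    sample = row[row.estimator == "sample"]["mean"].iloc[0]
    analytic = expected_sample_corr(0.8, 1.0, 1.0, nv, 5)
    print(f"{nv:5.1f}   {corrected:15.3f}   {sample:12.3f}   {analytic:21.3f}")

print(
    "\nThe corrected estimate stays at the generating value 0.8 at every\n"
    "noise level, while the sample correlation is attenuated toward zero\n"
    "exactly as the closed-form expectation gamma/(sigma^2 + noise/n) predicts."
)
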