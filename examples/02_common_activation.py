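"""Separating a shared activation component from stimulus-specific patterns.

Adds a common activation component (variance 4) to every trial of the
3-stimulus design plus a 5-trial control condition that measures it alone.
The model constrains the common component to be uncorrelated with the
stimulus components; the corrected correlations then recover the true
similarity structure, while plain sample correlations are dominated by the
shared component and the fixed-effects control subtraction stays biased.
"""

from pcmodel import RunConfig, run_scenario_grid

_, summary = run_scenario_grid(
    RunConfig(scenario="common_activation", replicates=100, seed=0,
              grid={"noise_var": (0.5, 5.0)})
)

truth = {"rho12": 0.0, "rho13": -0.2, "rho23": 0.8}
for nv in (0.5, 5.0):
    print(f"\nnoise variance {nv}")
    print("pair    truth   sample   control-subtracted   corrected")
    for name, t in truth.items():
        row = summary[(summary.noise_var == nv) & (summary.name == name)]
        get = lambda est: row[row.estimator == est]["mean"].iloc[0]
        print(f"{name}  {t:6.1f}   {get('sample'):6.3f}   "
              f"{get('control_subtracted'):18.3f}   {get('corrected'):9.3f}")

print(
    "\nSample correlations are pushed strongly positive by the common\n"
    "component; subtracting the measured control pattern leaks its noise\n"
    "into every residual (bias grows with the noise level); the model-based\n"
    "decomposition recovers the generating correlations."
)
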