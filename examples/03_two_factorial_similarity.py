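"""Matched-level similarity in a 2 x 4 factorial design.

Two conditions (e.g. movement vs. stimulation) across four levels (e.g.
fingers): per-condition common components (variance 2, covariance
gamma_alpha) plus level-specific components (variance 1) that share a
covariance of 0.5 only between matching levels.  The corrected
matched-level correlation gamma_beta/(sigma_beta1 sigma_beta2) = 0.5 is the
quantity of interest; naive strategies confound it with the common
covariance and the noise level.
"""

from pcmodel import RunConfig, run_scenario_grid

_, summary = run_scenario_grid(
    RunConfig(scenario="two_factorial", replicates=100, seed=0,
              grid={"noise_var": (0.5, 8.0), "gamma_alpha_ratio": (0.0, 0.9)})
)

print("noise  gamma_a/sigma_a^2  sample(match)  match-nonmatch  cond-mean-subtr  corrected")
for _, row0 in summary[(summary.estimator == "corrected")
                       & (summary.name == "rho_beta")].iterrows():
    nv, ga = row0.noise_var, row0.gamma_alpha_ratio
    sel = summary[(summary.noise_var == nv) & (summary.gamma_alpha_ratio == ga)
                  & (summary.name == "rho_beta")]
    get = lambda est: sel[sel.estimator == est]["mean"].iloc[0]
    print(f"{nv:5.1f}  {ga:17.2f}  {get('sample_matched'):13.3f}  "
          f"{get('corr_difference'):14.3f}  {get('cond_mean_subtracted'):15.3f}  "
          f"{get('corrected'):9.3f}")

print(
    "\nOnly the model-based estimate sits at the generating value 0.5 in\n"
    "every cell: the matched sample correlation rises with the common\n"
    "covariance, the matched-minus-nonmatched difference and the\n"
    "condition-mean-subtracted correlation both shrink as noise grows."
)
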