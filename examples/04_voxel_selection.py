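"""Robustness to uninformative voxels.

In the 2 x 4 factorial design, a growing fraction of voxels carries no
level-specific signal (their level components are zeroed).  Naive
correlation estimates fall as the region is diluted; the corrected
matched-level correlation stays at the generating value because the
estimated variance and covariance shrink together.
"""

from pcmodel import RunConfig, run_scenario_grid

_, summary = run_scenario_grid(
    RunConfig(scenario="voxel_selection", replicates=100, seed=0)
)

print("uninformative fraction  match-nonmatch  cond-mean-subtr  corrected")
for frac in (0.0, 0.25, 0.5, 0.75):
    sel = summary[(summary.fraction == frac) & (summary.name == "rho_beta")]
    get = lambda est: sel[sel.estimator == est]["mean"].iloc[0]
    print(f"{frac:22.2f}  {get('corr_difference'):14.3f}  "
          f"{get('cond_mean_subtracted'):15.3f}  {get('corrected'):9.3f}")

print(
    "\nWith 75% uninformative voxels the naive estimates have fallen by more\n"
    "than half, while the corrected correlation remains near 0.5 -- the\n"
    "property that makes correlations comparable across regions with\n"
    "different voxel composition."
)
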