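"""Scenario-grid driver: simulate -> fit -> estimators, tidied into tables.

For every grid point and replicate the driver draws a dataset from the
scenario's generative model, fits the scenario's component model by EM
(replicates are batched into one vectorized EM run), and evaluates the
corrected and naive similarity estimators (plus spatial-kernel estimates
for the spherical scenario).  Results are returned as a tidy table
(one row per replicate x estimator) and a summary table (mean, standard
error, convergence rate per grid cell), and optionally written as TSV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate
from .estimation import FittedModel, blup_patterns, em_fit_replicates, remove_mean
from .models import ParameterVector, PatternDataset, assemble_G
from .similarity import (
    condition_mean_subtracted_corr,
    control_subtracted_corr,
    corrected_correlations,
    sample_corr_mean_patterns,
)
from .spatial import spatial_estimates

__all__ = ["RunConfig", "run_scenario_grid", "SCENARIO_GRIDS"]

SCENARIO_GRIDS: dict[str, dict[str, tuple]] = {
    "one_factorial": {"noise_var": simulate.ONEFACT_NOISE_GRID},
    "common_activation": {"noise_var": simulate.ONEFACT_NOISE_GRID},
    "two_factorial": {
        "noise_var": simulate.TWOFACT_NOISE_GRID,
        "gamma_alpha_ratio": simulate.TWOFACT_GAMMA_RATIO_GRID,
    },
    "voxel_selection": {"fraction": simulate.VOXEL_FRACTION_GRID},
    "spatial": {
        "s_beta": simulate.SPATIAL_S_GRID,
        "s_eps": simulate.SPATIAL_S_GRID,
    },
}


@dataclass
class RunConfig:
    """Options for one scenario-grid run.

    ``grid`` overrides the scenario's default parameter grid; ``tol`` and
    ``max_iter`` are forwarded to the EM fits.  All seeds derive from
    ``seed`` -- two runs with identical configs produce identical tables.
    """

    scenario: str
    replicates: int = 100
    seed: int = 0
    grid: dict[str, tuple] = field(default_factory=dict)
    out_dir: str | None = None
    tol: float = 1e-8
    max_iter: int = 1000
    stability_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_GRIDS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; known: {sorted(SCENARIO_GRIDS)}"
            )
        if self.replicates < 0:
            raise ValueError("replicates must be >= 0")


def _draw(scenario: str, grid_kw: dict, rng) -> tuple[PatternDataset, simulate.ScenarioTruth]:
    if scenario == "one_factorial":
        return simulate.scenario_one_factorial(noise_var=grid_kw["noise_var"], seed=rng)
    if scenario == "common_activation":
        return simulate.scenario_common_activation(noise_var=grid_kw["noise_var"], seed=rng)
    if scenario == "two_factorial":
        return simulate.scenario_two_factorial(
            noise_var=grid_kw["noise_var"],
            gamma_alpha=grid_kw["gamma_alpha_ratio"] * 2.0,  # sigma_alpha^2 = 2
            seed=rng,
        )
    if scenario == "voxel_selection":
        return simulate.scenario_voxel_selection(fraction=grid_kw["fraction"], seed=rng)
    if scenario == "spatial":
        return simulate.scenario_spatial(
            s_beta=grid_kw["s_beta"], s_eps=grid_kw["s_eps"], seed=rng
        )
    raise ValueError(scenario)


def _matched_nonmatched(corr: pd.DataFrame, n_levels: int = 4) -> tuple[float, float]:
    """Mean cross-condition correlation for matching / non-matching levels."""
    matched, nonmatched = [], []
    for i in range(1, n_levels + 1):
        for j in range(1, n_levels + 1):
            v = corr.loc[f"c1l{i}", f"c2l{j}"]
            (matched if i == j else nonmatched).append(v)
    return float(np.nanmean(matched)), float(np.nanmean(nonmatched))


def _estimators(
    scenario: str,
    data: PatternDataset,
    truth: simulate.ScenarioTruth,
    fitted: FittedModel,
    floor: float,
) -> list[tuple[str, str, float]]:
    out: list[tuple[str, str, float]] = []
    res = corrected_correlations(fitted.G, floor=floor)
    for name, (i, j, _true) in truth.target_correlations.items():
        out.append(("corrected", name, float(res.corrected[i, j])))

    if scenario in ("one_factorial", "common_activation"):
        sc = sample_corr_mean_patterns(data)
        for name, (i, j, _t) in truth.target_correlations.items():
            a, b = (i, j) if scenario == "one_factorial" else (i - 1, j - 1)
            out.append(("sample", name, float(sc.loc[f"s{a + 1}", f"s{b + 1}"])))
        if scenario == "common_activation":
            cs = control_subtracted_corr(data, "control")
            for name, (i, j, _t) in truth.target_correlations.items():
                a, b = i - 1, j - 1
                out.append(
                    ("control_subtracted", name, float(cs.loc[f"s{a + 1}", f"s{b + 1}"]))
                )
    elif scenario in ("two_factorial", "voxel_selection"):
        sc = sample_corr_mean_patterns(data)
        m, nm = _matched_nonmatched(sc)
        out += [
            ("sample_matched", "rho_beta", m),
            ("sample_nonmatched", "rho_beta", nm),
            ("corr_difference", "rho_beta", m - nm),
        ]
        cm = condition_mean_subtracted_corr(data)
        m2, _ = _matched_nonmatched(cm)
        out.append(("cond_mean_subtracted", "rho_beta", m2))
    elif scenario == "spatial":
        G = fitted.G
        out += [
            ("variance", "sigma_alpha1_sq", float(G[0, 0])),
            ("variance", "sigma_alpha2_sq", float(G[1, 1])),
            ("variance", "sigma_beta1_sq", float(G[2, 2])),
            ("variance", "sigma_beta2_sq", float(G[6, 6])),
            ("variance", "sigma_eps_sq", float(fitted.params.noise_var)),
        ]
        _, Yc = remove_mean(data, truth.model)
        U_hat = blup_patterns(fitted, Yc, truth.model)
        resid = Yc - truth.model.Z @ U_hat
        ests = spatial_estimates(U_hat, resid, truth.model.blocks, data.coords)
        for block in ("condition", "level", "noise"):
            out.append(("kernel_sd", f"s_{block}", float(ests[block].s)))
            out.append(("kernel_fwhm", f"fwhm_{block}", float(ests[block].fwhm)))
    return out


def run_scenario_grid(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a full scenario grid; returns (tidy, summary) tables.

    With ``config.out_dir`` set, writes ``<scenario>_tidy.tsv`` and
    ``<scenario>_summary.tsv`` there (with a provenance header).
    """
    grids = {**SCENARIO_GRIDS[config.scenario], **config.grid}
    keys = list(grids)
    points = list(itertools.product(*(grids[k] for k in keys)))
    base = np.random.SeedSequence(config.seed)
    cell_seeds = base.spawn(len(points))

    rows: list[dict] = []
    for gp, (point, cell_ss) in enumerate(zip(points, cell_seeds)):
        grid_kw = dict(zip(keys, point))
        rep_seeds = cell_ss.spawn(max(config.replicates, 1))
        datasets, truths = [], []
        for r in range(config.replicates):
            d, t = _draw(config.scenario, grid_kw, np.random.default_rng(rep_seeds[r]))
            datasets.append(d)
            truths.append(t)
        if config.replicates == 0:
            continue
        model = truths[0].model
        Ys = np.stack([d.Y for d in datasets])
        theta, sig2, ll, conv = em_fit_replicates(
            Ys, model, tol=config.tol, max_iter=config.max_iter
        )
        for r in range(config.replicates):
            params = ParameterVector(theta=theta[r], noise_var=sig2[r])
            fitted = FittedModel(
                params=params,
                G=assemble_G(model, params),
                mean_coef=np.zeros(model.n_components),
                loglik_trace=np.array([ll[r]]),
                U_hat=None,
                n_iter=0,
                converged=bool(conv[r]),
            )
            for est, name, value in _estimators(
                config.scenario, datasets[r], truths[r], fitted, config.stability_floor
            ):
                rows.append(
                    dict(
                        scenario=config.scenario,
                        **grid_kw,
                        replicate=r,
                        estimator=est,
                        name=name,
                        value=value,
                        converged=bool(conv[r]),
                    )
                )

    cols = ["scenario", *keys, "replicate", "estimator", "name", "value", "converged"]
    tidy = pd.DataFrame(rows, columns=cols)
    if len(tidy):
        g = tidy.groupby([*keys, "estimator", "name"], sort=False)
        summary = g.agg(
            mean=("value", "mean"),
            se=("value", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
            n=("value", "size"),
            convergence_rate=("converged", "mean"),
        ).reset_index()
    else:
        summary = pd.DataFrame(
            columns=[*keys, "estimator", "name", "mean", "se", "n", "convergence_rate"]
        )

    if config.out_dir is not None:
        from .io import write_table  # local import to avoid a cycle

        write_table(tidy, f"{config.out_dir}/{config.scenario}_tidy.tsv",
                    seed=config.seed, config=vars(config))
        write_table(summary, f"{config.out_dir}/{config.scenario}_summary.tsv",
                    seed=config.seed, config=vars(config))
    return tidy, summary
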