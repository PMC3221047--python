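"""Reading and writing datasets, model specifications, and fit results.

All on-disk formats are plain text: TSV (tab-delimited, header row, '.'
decimal) for matrices and tables, JSON for structured objects.  Output
files carry a provenance comment header (tool version, seed, config hash)
and are written atomically -- a malformed run never leaves a partial file
behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile

import numpy as np
import pandas as pd

from . import __version__
from .estimation import FittedModel
from .exceptions import InvalidDesignError
from .models import (
    ComponentModel,
    ParameterVector,
    PatternDataset,
    build_common_pattern,
    build_factorial,
    build_one_factorial,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "model_from_json",
    "model_to_json",
    "save_fit",
    "load_fit",
    "write_table",
]

_BUILDERS = {
    "one_factorial": build_one_factorial,
    "common_pattern": build_common_pattern,
    "factorial": build_factorial,
}


def _provenance(seed=None, config=None) -> str:
    h = ""
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        h = f" config_hash={digest}"
    s = f" seed={seed}" if seed is not None else ""
    return f"# pcmodel v{__version__}{s}{h}\n"


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str, seed=None, config=None) -> None:
    """Write a DataFrame as TSV with a provenance header, atomically."""
    _atomic_write(path, _provenance(seed, config) + df.to_csv(sep="\t", index=False))


def read_dataset(
    data_path: str, meta_path: str, coords_path: str | None = None
) -> PatternDataset:
    """Load a trial-by-voxel TSV plus trial metadata (and optional coordinates).

    The data file has one header row of voxel labels; the metadata file has
    columns ``trial``, ``condition`` and optionally ``run``; the
    coordinates file has columns ``voxel_id``, ``x``, ``y``, ``z``.
    """
    data = pd.read_csv(data_path, sep="\t", comment="#", float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"condition": str})
    if "condition" not in meta.columns or "trial" not in meta.columns:
        raise InvalidDesignError("metadata must have 'trial' and 'condition' columns")
    if len(meta) != len(data):
        raise InvalidDesignError(
            f"metadata has {len(meta)} rows but data has {len(data)} trials"
        )
    if meta["trial"].duplicated().any():
        raise InvalidDesignError("duplicate trial ids in metadata")
    Y = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise InvalidDesignError("non-numeric or non-finite cells in data")
    coords = None
    if coords_path is not None:
        ctab = pd.read_csv(coords_path, sep="\t", comment="#")
        missing = {"x", "y", "z"} - set(ctab.columns)
        if missing:
            raise InvalidDesignError(f"coords file lacks columns {sorted(missing)}")
        if len(ctab) != Y.shape[1]:
            raise InvalidDesignError(
                f"coords has {len(ctab)} rows but data has {Y.shape[1]} voxels"
            )
        coords = ctab[["x", "y", "z"]].to_numpy(dtype=float)
    run = meta["run"].to_numpy() if "run" in meta.columns else None
    return PatternDataset(
        Y=Y, condition=meta["condition"].to_numpy(), run=run, coords=coords
    )


def write_dataset(
    data: PatternDataset,
    data_path: str,
    meta_path: str,
    coords_path: str | None = None,
    seed=None,
) -> None:
    """Write a dataset in the layout :func:`read_dataset` expects."""
    head = _provenance(seed)
    df = pd.DataFrame(data.Y, columns=[f"v{i}" for i in range(data.n_voxels)])
    _atomic_write(data_path, head + df.to_csv(sep="\t", index=False, float_format="%.17g"))
    meta = pd.DataFrame({"trial": np.arange(data.n_trials), "condition": data.condition})
    if data.run is not None:
        meta["run"] = data.run
    _atomic_write(meta_path, head + meta.to_csv(sep="\t", index=False))
    if coords_path is not None:
        if data.coords is None:
            raise InvalidDesignError("dataset has no coordinates to write")
        ctab = pd.DataFrame(data.coords, columns=["x", "y", "z"])
        ctab.insert(0, "voxel_id", np.arange(len(ctab)))
        _atomic_write(coords_path, head + ctab.to_csv(sep="\t", index=False))


def model_to_json(model: ComponentModel) -> dict:
    """Serializable model spec: builder provenance when available, else dense."""
    if model.meta.get("builder"):
        return {"builder": model.meta["builder"], "args": model.meta["args"]}
    return {
        "Z": model.Z.tolist(),
        "basis": model.basis.tolist(),
        "param_names": model.param_names,
        "blocks": {k: list(v) for k, v in model.blocks.items()},
        "component_names": model.component_names,
    }


def model_from_json(spec: dict | str) -> ComponentModel:
    """Build a component model from a spec dict or a JSON file path."""
    if isinstance(spec, str):
        with open(spec) as fh:
            spec = json.load(fh)
    if "builder" in spec:
        name = spec["builder"]
        if name not in _BUILDERS:
            raise InvalidDesignError(f"unknown builder {name!r}")
        args = dict(spec.get("args", {}))
        if name == "common_pattern" and "anchor_pairs" in args:
            args["anchor_pairs"] = [tuple(p) for p in args["anchor_pairs"]]
        return _BUILDERS[name](**args)
    required = {"Z", "basis", "param_names", "blocks", "component_names"}
    missing = required - set(spec)
    if missing:
        raise InvalidDesignError(f"model spec lacks keys {sorted(missing)}")
    return ComponentModel(
        Z=np.asarray(spec["Z"], float),
        basis=np.asarray(spec["basis"], float),
        param_names=list(spec["param_names"]),
        blocks={k: list(v) for k, v in spec["blocks"].items()},
        component_names=list(spec["component_names"]),
    )


def save_fit(fitted: FittedModel, model: ComponentModel, path: str, seed=None) -> None:
    """Serialize a fit result (theta, G, noise variance, trace) as JSON."""
    payload = {
        "pcmodel_version": __version__,
        "seed": seed,
        "model": model_to_json(model),
        "theta": fitted.params.theta.tolist(),
        "param_names": model.param_names,
        "noise_var": fitted.params.noise_var,
        "G": fitted.G.tolist(),
        "component_names": model.component_names,
        "mean_coef": fitted.mean_coef.tolist(),
        "loglik_trace": np.asarray(fitted.loglik_trace, float).tolist(),
        "n_iter": fitted.n_iter,
        "converged": fitted.converged,
    }
    _atomic_write(path, json.dumps(payload, indent=1) + "\n")


def load_fit(path: str) -> tuple[FittedModel, ComponentModel]:
    """Load a fit result written by :func:`save_fit`."""
    with open(path) as fh:
        payload = json.load(fh)
    model = model_from_json(payload["model"])
    params = ParameterVector(
        theta=np.asarray(payload["theta"], float),
        noise_var=float(payload["noise_var"]),
    )
    fitted = FittedModel(
        params=params,
        G=np.asarray(payload["G"], float),
        mean_coef=np.asarray(payload["mean_coef"], float),
        loglik_trace=np.asarray(payload["loglik_trace"], float),
        U_hat=None,
        n_iter=int(payload["n_iter"]),
        converged=bool(payload["converged"]),
    )
    return fitted, model
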