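"""Serialisation: JSON model specs and fit results, TSV timeseries and timings."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .design import ConditionTiming
from .integrate import Prediction
from .inversion import FitResult
from .model import GaussianDensity, ModelSpec, ParamEntry

__all__ = [
    "spec_to_dict", "spec_from_dict", "write_spec", "read_spec",
    "write_timeseries", "read_timeseries",
    "write_timings", "read_timings",
    "fit_result_to_dict", "fit_result_from_dict", "write_fit_result", "read_fit_result",
]

SCHEMA_VERSION = 1


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "region_names": spec.region_names,
        "condition_names": spec.condition_names,
        "a_mask": spec.a_mask.tolist(),
        "b_masks": spec.b_masks.tolist(),
        "c_mask": spec.c_mask.tolist(),
        "TR": spec.TR,
        "TE": spec.TE,
        "slice_times": spec.slice_times.tolist(),
        "n_confounds": spec.n_confounds,
    }


def spec_from_dict(d: dict) -> ModelSpec:
    try:
        return ModelSpec(
            region_names=d["region_names"],
            condition_names=d["condition_names"],
            a_mask=np.asarray(d["a_mask"]),
            b_masks=np.asarray(d["b_masks"]),
            c_mask=np.asarray(d["c_mask"]),
            TR=float(d["TR"]),
            TE=float(d["TE"]),
            slice_times=np.asarray(d["slice_times"]) if d.get("slice_times") is not None else None,
            n_confounds=int(d.get("n_confounds", 1)),
        )
    except KeyError as err:
        raise ValueError(f"model spec is missing required field {err.args[0]!r}") from err


def write_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec_to_dict(spec), fh, indent=2)


def read_spec(path) -> ModelSpec:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as err:
            raise ValueError(f"{path}: malformed JSON at line {err.lineno}: {err.msg}") from err
    return spec_from_dict(d)


def write_timeseries(Y: np.ndarray, region_names, path) -> None:
    """Timeseries as TSV, header row of region names, one row per volume."""
    pd.DataFrame(np.asarray(Y), columns=list(region_names)).to_csv(
        path, sep="\t", index=False)


def read_timeseries(path) -> tuple[np.ndarray, list]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ValueError(f"{path}: could not parse TSV timeseries: {err}") from err
    if df.empty:
        raise ValueError(f"{path}: timeseries file holds no rows")
    return df.to_numpy(dtype=float), list(df.columns)


def write_timings(timings: list, path) -> None:
    rows = [
        {"condition": t.name, "onset": o, "duration": d}
        for t in timings for o, d in zip(t.onsets, t.durations)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_timings(path) -> list:
    """Condition timings from a TSV with columns condition, onset, duration."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ValueError(f"{path}: could not parse TSV timings: {err}") from err
    for col in ("condition", "onset", "duration"):
        if col not in df.columns:
            raise ValueError(f"{path}: timing file lacks required column {col!r}")
    out = []
    for name, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("onset")
        out.append(ConditionTiming(str(name),
                                   tuple(grp["onset"].astype(float)),
                                   tuple(grp["duration"].astype(float))))
    return out


def _entry_to_dict(e: ParamEntry) -> dict:
    return {"family": e.family, "index": list(e.index), "label": e.label,
            "units": e.units, "prior_variance": e.prior_variance,
            "prior_mean": e.prior_mean}


def fit_result_to_dict(result: FitResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "posterior_mean": result.posterior.mean.tolist(),
        "posterior_cov": result.posterior.cov.tolist(),
        "index": [_entry_to_dict(e) for e in result.posterior.index],
        "lambdas": result.lambdas.tolist(),
        "lambda_var": result.lambda_var.tolist(),
        "F": result.F,
        "F_trajectory": result.F_trajectory.tolist(),
        "accuracy": result.accuracy,
        "complexity": result.complexity,
        "y_hat": result.prediction.y_hat.tolist(),
        "residuals": result.residuals.tolist(),
        "converged": result.converged,
        "n_iterations": result.n_iterations,
    }


def fit_result_from_dict(d: dict) -> FitResult:
    index = [ParamEntry(family=e["family"], index=tuple(e["index"]),
                        label=e["label"], units=e["units"],
                        prior_variance=e["prior_variance"],
                        prior_mean=e.get("prior_mean", 0.0))
             for e in d["index"]]
    posterior = GaussianDensity(np.asarray(d["posterior_mean"]),
                                np.asarray(d["posterior_cov"]), index)
    return FitResult(
        posterior=posterior,
        lambdas=np.asarray(d["lambdas"]),
        lambda_var=np.asarray(d["lambda_var"]),
        F=float(d["F"]),
        F_trajectory=np.asarray(d["F_trajectory"]),
        accuracy=float(d["accuracy"]),
        complexity=float(d["complexity"]),
        prediction=Prediction(y_hat=np.asarray(d["y_hat"])),
        residuals=np.asarray(d["residuals"]),
        converged=bool(d["converged"]),
        n_iterations=int(d["n_iterations"]),
    )


def write_fit_result(result: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(result), fh)


def read_fit_result(path) -> FitResult:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as err:
            raise ValueError(f"{path}: malformed JSON at line {err.lineno}: {err.msg}") from err
    return fit_result_from_dict(d)
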