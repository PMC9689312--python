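"""Delimited-text dataset formats and the model validation report.

Datasets are plain CSV with a controlled header vocabulary (``time_h``,
``X_gL``, ``S_gL``, ``E_gL``, ``CO2_L``, ``VDK_ppm``) plus a YAML sidecar
(``<path>.meta.yaml``) carrying the design, noise level, seed, and model
id.  Validation reports the weighted cost residual J and per-variable
relative RMSEs — root-mean-square residuals normalized by each variable's
measured maximum, the same normalization the WLS objective uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import MeasurementSet
from .estimate import fit_initial_conditions
from .params import MODEL_VARIABLES, as_dict
from .simulate import COLUMN_NAMES, ExperimentDesign, integrate, observe

__all__ = [
    "read_dataset",
    "write_dataset",
    "relative_rmse",
    "ValidationReport",
    "validation_report",
]

_NAME_FROM_COLUMN = {v: k for k, v in COLUMN_NAMES.items()}


def write_dataset(dataset: MeasurementSet, path) -> None:
    """Write a measurement set as CSV plus a YAML descriptor sidecar."""
    path = Path(path)
    table = dataset.data.copy()
    table.columns = [COLUMN_NAMES[v] for v in table.columns]
    table.index.name = COLUMN_NAMES["time"]
    table.to_csv(path, float_format="%.12g")
    d = dataset.design
    meta = {
        "model_id": dataset.model_id,
        "provenance": dataset.provenance,
        "sigma_rel": {k: float(v) for k, v in dataset.sigma_rel.items()},
        "seed": dataset.seed,
        "truncated_at_zero": dataset.truncated_at_zero,
        "design": {
            "id": d.id, "duration": d.duration, "temperature": d.temperature,
            "S0": d.S0, "X0": d.X0, "E0": d.E0, "CO2_0": d.CO2_0, "VDK0": d.VDK0,
        },
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_dataset(path, design: ExperimentDesign | None = None,
                 model_id: str | None = None) -> MeasurementSet:
    """Read a CSV dataset (and its sidecar when present).

    Either the sidecar or explicit ``design``/``model_id`` must supply the
    batch context.  Unknown columns raise with the offending name; times
    must be strictly increasing; missing cells are preserved as NaN.
    """
    path = Path(path)
    table = pd.read_csv(path)
    unknown = [c for c in table.columns if c not in _NAME_FROM_COLUMN]
    if unknown:
        raise ValueError(f"unknown column(s) {unknown}; allowed: {sorted(_NAME_FROM_COLUMN)}")
    if COLUMN_NAMES["time"] not in table.columns:
        raise ValueError(f"missing required column {COLUMN_NAMES['time']!r}")
    table = table.set_index(COLUMN_NAMES["time"])
    table.columns = [_NAME_FROM_COLUMN[c] for c in table.columns]

    meta_path = Path(str(path) + ".meta.yaml")
    sigma, seed, provenance = {}, None, "external"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        model_id = model_id or meta.get("model_id")
        sigma = meta.get("sigma_rel", {})
        seed = meta.get("seed")
        provenance = meta.get("provenance", "external")
        if design is None and "design" in meta:
            design = ExperimentDesign(**meta["design"])
    if design is None or model_id is None:
        raise ValueError("design and model_id required (no sidecar descriptor found)")
    keep = [c for c in table.columns if c in MODEL_VARIABLES[model_id]]
    return MeasurementSet(
        model_id, design, table[keep], sigma, seed, provenance
    )


def relative_rmse(predictions: pd.DataFrame, dataset: MeasurementSet) -> pd.Series:
    """Per-variable relative RMSE: ``sqrt(mean(((y - yhat)/max_i y)^2))``.

    ``predictions`` must share the dataset's sample times (aligned index).
    """
    common = dataset.data.index.intersection(predictions.index)
    if len(common) == 0:
        raise ValueError("no common sample times between predictions and data")
    y = dataset.data.loc[common]
    yhat = predictions.loc[common, dataset.variables]
    maxima = dataset.data.abs().max(skipna=True)
    scaled = (y - yhat) / maxima
    return np.sqrt((scaled**2).mean(skipna=True))


@dataclass
class ValidationReport:
    """Fit-quality summary: cost residual J and relative RMSEs.

    ``mode`` is ``"direct"`` (prediction on the training batches) or
    ``"cross"`` (held-out batch with only its initial conditions
    re-estimated).
    """

    model_id: str
    mode: str
    J: float
    per_experiment: pd.DataFrame      # rows: experiment id, columns: variables
    global_rmse: pd.Series
    ic_overrides: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_experiment.copy()
        out.loc["global"] = self.global_rmse
        return out

    def __str__(self) -> str:
        return (
            f"{self.mode} validation, {self.model_id} model: J = {self.J:.4g}\n"
            + self.to_frame().to_string(float_format=lambda v: f"{v:.3g}")
        )


def validation_report(
    params: Mapping[str, float],
    datasets: Sequence[MeasurementSet] | MeasurementSet,
    model_id: str,
    mode: str = "direct",
    seed: int | None = None,
) -> ValidationReport:
    """Validate a parameter set against one or more measurement sets.

    Direct mode simulates each batch from its nominal design; cross mode
    first re-estimates the batch's initial conditions with the parameters
    frozen (the held-out-experiment protocol).  The global RMSE pools the
    normalized residuals of all experiments before taking the root mean
    square.
    """
    from .estimate import _apply_ics, _as_list

    datasets = _as_list(datasets)
    params = as_dict(params)
    if mode not in ("direct", "cross"):
        raise ValueError("mode must be 'direct' or 'cross'")

    ics: dict[str, dict[str, float]] = {}
    if mode == "cross":
        for ds in datasets:
            fit = fit_initial_conditions(ds, model_id, params, seed=seed)
            ics.update(fit.ic_overrides)

    rows, pooled = {}, {}
    J = 0.0
    for ds in datasets:
        design = _apply_ics(ds.design, model_id, ics.get(ds.design.id, {}))
        traj = integrate(model_id, params, design, t_grid=ds.times)
        pred = observe(traj, ds.variables, ds.times)
        rows[ds.design.id] = relative_rmse(pred, ds)
        maxima = ds.data.abs().max(skipna=True)
        scaled = ((ds.data - pred) / maxima).to_numpy(dtype=float)
        for v, col in zip(ds.variables, scaled.T):
            pooled.setdefault(v, []).append(col[np.isfinite(col)])
        J += float(np.nansum(scaled[np.isfinite(scaled)] ** 2))
    per_exp = pd.DataFrame(rows).T
    global_rmse = pd.Series(
        {v: np.sqrt(np.mean(np.concatenate(cols) ** 2)) for v, cols in pooled.items()}
    )
    return ValidationReport(model_id, mode, J, per_exp, global_rmse, ics)
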