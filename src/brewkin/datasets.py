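"""Synthetic measurement sets emulating the four reference batch experiments.

The real campaign behind the packaged parameter defaults is not publicly
deposited, so the pipeline is exercised on synthetic data: four batch
designs (:func:`default_designs`), an early-dense/late-sparse sampling
schedule (:func:`sampling_schedule`, samples every ~2.5 h during the first
36 h while the dynamics are fast, then every 8 h), and a relative-error
noise model in which each variable's additive Gaussian noise has standard
deviation proportional to that variable's trajectory maximum — the error
structure the weighted least-squares objective assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import MODEL_VARIABLES
from .simulate import ExperimentDesign, integrate, observe

__all__ = ["MeasurementSet", "default_designs", "sampling_schedule", "make_dataset"]


@dataclass
class MeasurementSet:
    """Sampled (possibly noisy) observations of one batch.

    ``data`` has one column per observed variable, indexed by sample time;
    ``sigma_rel`` records the relative noise level per variable (0 for
    noise-free) and ``provenance`` whether the set was generated here or
    read from an external file.  Noise is truncated at zero (concentrations
    cannot be negative); the descriptor keeps that fact on record.
    """

    model_id: str
    design: ExperimentDesign
    data: pd.DataFrame
    sigma_rel: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    provenance: str = "synthetic"
    truncated_at_zero: bool = True

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("a measurement set needs at least one sample")
        t = self.data.index.to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        bad = [v for v in self.data.columns if v not in MODEL_VARIABLES[self.model_id]]
        if bad:
            raise ValueError(
                f"variables {bad} do not belong to model {self.model_id!r}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)


def default_designs() -> list[ExperimentDesign]:
    """The four reference batch designs (duration h, T degC, S0 and X0 g/L)."""
    return [
        ExperimentDesign("1", 72.0, 19.0, 88.0, 0.705),
        ExperimentDesign("2", 54.0, 19.0, 72.0, 0.529),
        ExperimentDesign("3", 96.0, 21.0, 75.0, 0.705),
        ExperimentDesign("4", 72.0, 28.0, 81.0, 0.705),
    ]


def sampling_schedule(
    duration: float,
    dt_early: float = 2.5,
    t_switch: float = 36.0,
    dt_late: float = 8.0,
) -> np.ndarray:
    """Sample times: dense every ``dt_early`` h up to ``t_switch``, then sparse.

    Starts at 0, steps by ``dt_early`` while below ``min(t_switch,
    duration)``, includes the switch time, then steps by ``dt_late``;
    the batch end is always included.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt_early <= 0 or dt_late <= 0:
        raise ValueError("sampling steps must be > 0")
    eps = 1e-9
    end_early = min(t_switch, duration)
    times = list(np.arange(0.0, end_early + eps, dt_early))
    if duration > t_switch + eps:
        if times[-1] < t_switch - eps:
            times.append(t_switch)
        t = t_switch + dt_late
        while t < duration - eps:
            times.append(t)
            t += dt_late
    if times[-1] < duration - eps:
        times.append(duration)
    return np.asarray(times)


def make_dataset(
    model_id: str,
    params,
    design: ExperimentDesign,
    variables: Sequence[str] | None = None,
    sigma_rel: float | Mapping[str, float] = 0.0,
    seed: int | None = None,
    times: Sequence[float] | None = None,
) -> MeasurementSet:
    """Simulate ``design`` and sample it on the standard schedule with noise.

    Per variable j, ``y_j(ti) = ytrue_j(ti) + eps_ij`` with
    ``eps_ij ~ N(0, (sigma_rel_j * max_t ytrue_j)^2)``, truncated at zero.
    ``sigma_rel = 0`` returns the noise-free observations bit-exactly, and
    results are deterministic given ``seed``.
    """
    if variables is None:
        variables = list(MODEL_VARIABLES[model_id])
    sig = (
        {v: float(sigma_rel) for v in variables}
        if np.isscalar(sigma_rel)
        else {v: float(sigma_rel.get(v, 0.0)) for v in variables}
    )
    if any(s < 0 for s in sig.values()):
        raise ValueError("sigma_rel must be >= 0")
    if times is None:
        times = sampling_schedule(design.duration)
    traj = integrate(model_id, params, design)
    clean = observe(traj, variables, times)
    if all(s == 0 for s in sig.values()):
        return MeasurementSet(model_id, design, clean, sig, seed, "synthetic")
    rng = np.random.default_rng(seed)
    noisy = clean.copy()
    for v in variables:
        scale = sig[v] * float(clean[v].max())
        noisy[v] = np.maximum(clean[v].to_numpy() + rng.normal(0.0, scale, len(clean)), 0.0)
    return MeasurementSet(model_id, design, noisy, sig, seed, "synthetic")
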