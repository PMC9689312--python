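"""Batch integration of the fermentation models and output evaluation.

A batch is described by an :class:`ExperimentDesign` (isothermal temperature,
duration, initial sugar and biomass).  :func:`integrate` solves the chosen
model with a stiff-capable solver and dense output, returning a
:class:`Trajectory` from which :func:`observe` evaluates any subset of
output variables on arbitrary time grids without re-integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import co2_algebraic, make_rhs
from .params import CALIBRATED_T_RANGE, MODEL_STATES, MODEL_VARIABLES, as_dict

__all__ = ["ExperimentDesign", "Trajectory", "IntegrationError", "integrate", "observe"]

#: delimited-text column names for each in-memory variable
COLUMN_NAMES = {
    "time": "time_h",
    "X": "X_gL",
    "S": "S_gL",
    "E": "E_gL",
    "CO2": "CO2_L",
    "VDK": "VDK_ppm",
    "T": "temp_C",
}

#: default initial CO2 of the CO2 model (L); the logistic rate has a fixed
#: point at zero, so fermentation only starts from a strictly positive seed.
DEFAULT_CO2_0 = 0.1


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass
class ExperimentDesign:
    """Operating conditions of one isothermal batch."""

    id: str
    duration: float      # h
    temperature: float   # degC
    S0: float            # g/L
    X0: float            # g/L
    E0: float = 0.0      # g/L
    CO2_0: float | None = None  # L; None -> 0 (biomass model) / 0.1 (CO2 model)
    VDK0: float = 0.0    # ppm

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.S0 <= 0 or self.X0 <= 0:
            raise ValueError("S0 and X0 must be > 0")
        lo, hi = CALIBRATED_T_RANGE
        if not lo <= self.temperature <= hi:
            warnings.warn(
                f"temperature {self.temperature} degC outside calibrated range "
                f"[{lo}, {hi}]",
                RuntimeWarning,
                stacklevel=2,
            )

    def initial_state(self, model_id: str) -> np.ndarray:
        co2_0 = self.CO2_0
        if co2_0 is None:
            co2_0 = 0.0 if model_id == "biomass" else DEFAULT_CO2_0
        if model_id == "biomass":
            return np.array([self.X0, self.S0, self.E0, co2_0, self.VDK0])
        return np.array([co2_0, self.VDK0])

    def with_initial_state(self, model_id: str, y0: Sequence[float]) -> "ExperimentDesign":
        """Copy of the design with the initial state replaced (order as the model's)."""
        y0 = np.asarray(y0, dtype=float)
        if model_id == "biomass":
            return replace(self, X0=y0[0], S0=y0[1], E0=y0[2], CO2_0=y0[3], VDK0=y0[4])
        return replace(self, CO2_0=y0[0], VDK0=y0[1])


@dataclass
class Trajectory:
    """Dense solution of one batch plus a sampled state table.

    ``states`` holds every model variable (including the CO2 model's
    algebraic S and E) at the requested grid; the solver's dense-output
    object supports interpolation at arbitrary times via :func:`observe`.
    """

    model_id: str
    design: ExperimentDesign
    time: np.ndarray
    states: pd.DataFrame
    params: dict = field(repr=False)
    _sol: object = field(default=None, repr=False)

    @property
    def variables(self) -> tuple[str, ...]:
        return MODEL_VARIABLES[self.model_id]


def _eval_outputs(model_id, y, params, design) -> dict[str, np.ndarray]:
    """Map raw solver states to the model's output variables (clipped at 0)."""
    out: dict[str, np.ndarray] = {}
    if model_id == "biomass":
        for name, row in zip(MODEL_STATES["biomass"], y):
            out[name] = np.maximum(row, 0.0)
    else:
        co2 = np.maximum(y[0], 0.0)
        S, E = co2_algebraic(co2, params, design.S0, design.E0)
        out["CO2"] = co2
        out["S"] = np.maximum(np.atleast_1d(S), 0.0)
        out["E"] = np.maximum(np.atleast_1d(E), 0.0)
        out["VDK"] = np.maximum(y[1], 0.0)
    return out


def integrate(
    model_id: str,
    params,
    design: ExperimentDesign,
    t_grid: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate ``model_id`` over ``[0, design.duration]``.

    ``t_grid`` selects where the state table is evaluated (default: 201
    evenly spaced points); all grid times must lie inside the batch.  Tight
    default tolerances keep finite-difference sensitivities downstream
    accurate.  States are clipped at zero only in the reported table, never
    inside the solver.
    """
    if model_id not in MODEL_STATES:
        raise ValueError(f"unknown model_id {model_id!r}")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    p = as_dict(params)
    if t_grid is None:
        t_grid = np.linspace(0.0, design.duration, 201)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and (t_grid.min() < 0 or t_grid.max() > design.duration + 1e-9):
        raise ValueError("t_grid must lie within [0, duration]")

    fun = make_rhs(model_id, p, design.temperature, design.S0, design.E0)
    y0 = design.initial_state(model_id)

    sol = solve_ivp(
        fun,
        (0.0, design.duration),
        y0,
        method="LSODA",
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration of {model_id} model failed: {sol.message}",
            t_fail=float(sol.t[-1]) if sol.t.size else 0.0,
        )
    y = sol.sol(t_grid)
    states = pd.DataFrame(_eval_outputs(model_id, y, p, design), index=t_grid)
    states.index.name = "time_h"
    return Trajectory(model_id, design, t_grid, states, p, sol.sol)


def observe(
    traj: Trajectory, variables: Sequence[str], times: Sequence[float]
) -> pd.DataFrame:
    """Noise-free outputs of ``traj`` at ``times`` via dense-output interpolation.

    No extrapolation: every requested time must lie within the integrated
    span.  An empty variable list returns an empty table.
    """
    times = np.asarray(times, dtype=float)
    unknown = [v for v in variables if v not in traj.variables]
    if unknown:
        raise KeyError(
            f"unknown variable(s) {unknown} for model {traj.model_id!r}; "
            f"available: {list(traj.variables)}"
        )
    if times.size and (times.min() < 0 or times.max() > traj.design.duration + 1e-9):
        raise ValueError("requested times outside the integrated span")
    if not len(variables):
        return pd.DataFrame(index=pd.Index(times, name="time_h"))
    y = traj._sol(times)
    out = _eval_outputs(traj.model_id, np.atleast_2d(y), traj.params, traj.design)
    df = pd.DataFrame({v: out[v] for v in variables}, index=times)
    df.index.name = "time_h"
    return df
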