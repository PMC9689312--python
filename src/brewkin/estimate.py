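"""Weighted least-squares parameter identification for the fermentation models.

The objective is the classical WLS criterion

    J(theta) = sum_i (y(t_i) - y_model(t_i, theta))^T W^-1 (y(t_i) - y_model(t_i, theta))

summed over every sample of every experiment, where W is diagonal with the
squares of each variable's maximum measured value — i.e. residuals are
normalized per variable, matching a relative error model.  Minimization is
a two-step procedure: derivative-free simplex searches from (optionally
multi-start, log-uniform) initial draws, then a derivative-based
least-squares refinement from the best local minimum, which also yields the
residual Jacobian consumed by the uncertainty module.

Two staged recipes identify the temperature-dependent models from batches
run at several temperatures:

* biomass model — (a) all rates temperature-free, (b) the four
  temperature-law coefficients with everything else pinned, (c) global
  refinement of all ten parameters;
* CO2 model — (a) temperature-free rates with the poorly identifiable
  half-saturation KS pinned at an arbitrary value, (b) KS alone,
  (c) the five temperature-law coefficients, (d) global refinement.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize

from .datasets import MeasurementSet
from .models import co2_algebraic, make_rhs
from .params import MODEL_STATES, MODEL_VARIABLES, PARAM_NAMES, default_params, temperature_laws
from .simulate import IntegrationError

__all__ = [
    "ParameterSpec",
    "FitResult",
    "weight_matrix",
    "objective",
    "multi_start_fit",
    "staged_fit_biomass",
    "staged_fit_co2",
    "fit_initial_conditions",
    "default_bounds",
]

#: objective value returned when the model cannot be integrated at theta;
#: keeps derivative-free search alive instead of aborting the fit.
PENALTY = 1.0e6

#: states whose initial value can be appended to theta, per model
IC_STATE_NAMES = {
    "biomass": ("X0", "S0", "E0", "CO2_0", "VDK0"),
    "co2": ("CO2_0", "VDK0", "S0", "E0"),
}

_IC_DEFAULT_BOUNDS = {
    "X0": (1e-3, 20.0),
    "S0": (1.0, 300.0),
    "E0": (1e-6, 50.0),
    "CO2_0": (1e-3, 50.0),
    "VDK0": (1e-6, 10.0),
}


def _ic_name(design_id: str, state: str) -> str:
    return f"ic:{design_id}:{state}"


def _is_ic(name: str) -> bool:
    return name.startswith("ic:")


@dataclass
class ParameterSpec:
    """Free/fixed partition of the parameter vector theta.

    ``free`` lists the names estimated (model parameters, plus optional
    per-experiment initial conditions written ``"ic:<design id>:<state>"``,
    e.g. ``"ic:2:S0"``); ``fixed`` holds values for every other model
    parameter.  The union must cover the model's full parameter list,
    either through the temperature-law coefficients or through the
    temperature-free constants ``mu_max``/``r_vdk``.
    """

    model_id: str
    free: list[str]
    bounds: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        for name in self.free:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")
        names = set(self.free) | set(self.fixed)
        law = {"biomass": ("a", "b", "c", "d"), "co2": ("a", "b", "c", "d", "e")}[
            self.model_id
        ]
        stoich = [p for p in PARAM_NAMES[self.model_id] if p not in law]
        missing = [p for p in stoich if p not in names]
        law_ok = all(p in names for p in law) or {"mu_max", "r_vdk"} <= names
        if missing or not law_ok:
            raise ValueError(
                f"free+fixed must cover the full {self.model_id} parameter list; "
                f"missing {missing or list(law)}"
            )

    @property
    def P(self) -> int:
        return len(self.free)

    def decode(self, theta: np.ndarray):
        """Split a theta vector into (model parameter dict, IC overrides)."""
        params = dict(self.fixed)
        ics: dict[str, dict[str, float]] = {}
        for name, value in zip(self.free, theta):
            if _is_ic(name):
                _, design_id, state = name.split(":")
                ics.setdefault(design_id, {})[state] = float(value)
            else:
                params[name] = float(value)
        return params, ics

    def x0_from(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([values[name] for name in self.free], dtype=float)


@dataclass
class FitResult:
    """Outcome of one optimization (or of the final stage of a staged fit)."""

    model_id: str
    spec: ParameterSpec
    theta: dict[str, float]          # estimated free parameters
    params: dict[str, float]         # full model parameter dict at the optimum
    ic_overrides: dict[str, dict[str, float]]
    J: float
    residuals: list[pd.DataFrame]    # raw y - y_model per dataset
    jacobian: np.ndarray | None      # d(weighted residual)/d(theta_free)
    trace: list[dict]                # one entry per simplex start
    bounds_hit: dict[str, str]       # name -> "lower"/"upper"
    warnings: list[str] = field(default_factory=list)
    stage_history: list["FitResult"] | None = None

    @property
    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[n] for n in self.spec.free])


def weight_matrix(dataset: MeasurementSet) -> np.ndarray:
    """Diagonal weighting matrix W with squared per-variable measurement maxima."""
    maxima = dataset.data.abs().max(skipna=True)
    if maxima.isna().any():
        bad = list(maxima.index[maxima.isna()])
        raise ValueError(f"variable(s) {bad} have no finite observation")
    zero = list(maxima.index[maxima == 0])
    if zero:
        raise ValueError(f"degenerate weight: variable(s) {zero} are identically zero")
    return np.diag(maxima.to_numpy(dtype=float) ** 2)


def _apply_ics(design, model_id, overrides: Mapping[str, float]):
    return dataclasses.replace(design, **overrides) if overrides else design


def predict_outputs(model_id, params, design, times, variables,
                    rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Model outputs at ``times`` as an ``(M, N)`` array (fitting fast path).

    Numerically identical to :func:`brewkin.simulate.integrate` followed by
    :func:`~brewkin.simulate.observe`, but skips dense output and table
    construction — the WLS objective calls this thousands of times.
    """
    times = np.asarray(times, dtype=float)
    y0 = design.initial_state(model_id)
    fun = make_rhs(model_id, params, design.temperature, design.S0, design.E0)
    if times[-1] > 0:
        sol = solve_ivp(fun, (0.0, times[-1]), y0, method="LSODA",
                        t_eval=times, rtol=rtol, atol=atol)
        if not sol.success or sol.y.shape[1] != times.size:
            raise IntegrationError(
                f"integration of {model_id} model failed: {sol.message}",
                t_fail=float(sol.t[-1]) if sol.t.size else 0.0,
            )
        y = sol.y
    else:
        y = np.tile(y0[:, None], (1, times.size))
    states = MODEL_STATES[model_id]
    cols = []
    for v in variables:
        if model_id == "co2" and v in ("S", "E"):
            S, E = co2_algebraic(y[0], params, design.S0, design.E0)
            cols.append(S if v == "S" else E)
        else:
            cols.append(y[states.index(v)])
    return np.maximum(np.column_stack(cols), 0.0)


def _residual_arrays(theta, datasets, model_id, spec, rtol, atol):
    """Raw residual (y - y_model) arrays per dataset at theta."""
    params, ics = spec.decode(np.asarray(theta, dtype=float))
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for ds in datasets:
            design = _apply_ics(ds.design, model_id, ics.get(ds.design.id, {}))
            pred = predict_outputs(model_id, params, design, ds.times,
                                   ds.variables, rtol, atol)
            out.append(ds.data.to_numpy(dtype=float) - pred)
    return out


def _residual_frames(theta, datasets, model_id, spec, rtol, atol):
    """Raw residual (y - y_model) tables per dataset at theta."""
    arrays = _residual_arrays(theta, datasets, model_id, spec, rtol, atol)
    return [
        pd.DataFrame(a, index=ds.data.index, columns=ds.data.columns)
        for a, ds in zip(arrays, datasets)
    ]


def _weighted_residual_vector(arrays, datasets) -> np.ndarray:
    parts = []
    for arr, ds in zip(arrays, datasets):
        if isinstance(arr, pd.DataFrame):
            arr = arr.to_numpy(dtype=float)
        maxima = ds.data.abs().max(skipna=True).to_numpy(dtype=float)
        scaled = arr / maxima
        parts.append(scaled[np.isfinite(scaled)])
    return np.concatenate(parts)


def _as_list(datasets) -> list[MeasurementSet]:
    return [datasets] if isinstance(datasets, MeasurementSet) else list(datasets)


def objective(theta, datasets, model_id, spec: ParameterSpec,
              rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """WLS cost J(theta) pooled over all experiments and samples.

    Each experiment uses its own weighting matrix; missing observations
    (NaN cells) are skipped.  Integration failures return a large finite
    penalty rather than raising, so derivative-free search can continue.
    """
    datasets = _as_list(datasets)
    try:
        arrays = _residual_arrays(theta, datasets, model_id, spec, rtol, atol)
        r = _weighted_residual_vector(arrays, datasets)
    except (IntegrationError, FloatingPointError, OverflowError):
        return PENALTY
    J = float(r @ r)
    return J if np.isfinite(J) else PENALTY


def default_bounds(values: Mapping[str, float], factor: float = 100.0) -> dict:
    """Spread each value over ``[v/factor, v*factor]`` (sign-preserving)."""
    bounds = {}
    for name, v in values.items():
        if v > 0:
            bounds[name] = (v / factor, v * factor)
        elif v < 0:
            bounds[name] = (v * factor, v / factor)
        else:
            bounds[name] = (-1.0, 1.0)
    return bounds


def _log_uniform_draw(rng, lo, hi):
    """One draw per bound pair, log-uniform in magnitude when the sign is fixed."""
    out = np.empty(len(lo))
    for i, (a, b) in enumerate(zip(lo, hi)):
        if a > 0:
            out[i] = np.exp(rng.uniform(np.log(a), np.log(b)))
        elif b < 0:
            out[i] = -np.exp(rng.uniform(np.log(-b), np.log(-a)))
        else:
            out[i] = rng.uniform(a, b)
    return out


def multi_start_fit(
    datasets,
    model_id: str,
    spec: ParameterSpec,
    n_starts: int = 20,
    seed: int | None = None,
    x0: np.ndarray | Mapping[str, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    nm_maxiter: int | None = None,
) -> FitResult:
    """Two-step WLS minimization: multi-start simplex, then least-squares polish.

    Step (a) runs ``n_starts`` Nelder-Mead searches; the first start is
    ``x0`` when given, the rest are log-uniform draws within the bounds.
    Step (b) refines the best local minimum with a bounded trust-region
    least-squares solve on the weighted residual vector, whose Jacobian is
    kept for the Fisher-information analysis.  Deterministic given ``seed``.
    """
    datasets = _as_list(datasets)
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo = np.array([spec.bounds[n][0] for n in spec.free])
    hi = np.array([spec.bounds[n][1] for n in spec.free])
    if x0 is not None and not isinstance(x0, np.ndarray):
        x0 = spec.x0_from(x0) if isinstance(x0, Mapping) else np.asarray(x0, float)

    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(np.clip(x0, lo, hi))
    while len(starts) < n_starts:
        starts.append(_log_uniform_draw(rng, lo, hi))

    # optimize in units of the first start so parameters spanning orders of
    # magnitude are comparable to the simplex
    scale = np.maximum(np.abs(starts[0]), 1e-12)
    fun = lambda z: objective(z * scale, datasets, model_id, spec, rtol, atol)
    nm_bounds = list(zip(lo / scale, hi / scale))

    trace = []
    for k, start in enumerate(starts):
        res = minimize(
            fun,
            start / scale,
            method="Nelder-Mead",
            bounds=nm_bounds,
            options={
                "maxiter": nm_maxiter or 150 * spec.P,
                "maxfev": nm_maxiter or 150 * spec.P,
                "xatol": 1e-7,
                "fatol": 1e-11,
                "adaptive": spec.P > 4,
            },
        )
        trace.append(
            {"start": start.copy(), "theta": res.x * scale, "J": float(res.fun),
             "n_eval": int(res.nfev), "converged": bool(res.success)}
        )
    finite = [t for t in trace if t["J"] < PENALTY]
    if not finite:
        raise IntegrationError("all simplex starts failed to integrate the model")
    best = min(finite, key=lambda t: t["J"])

    n_res = _weighted_residual_vector(
        [ds.data * 0.0 for ds in datasets], datasets
    ).size

    def resid(z):
        try:
            arrays = _residual_arrays(z * scale, datasets, model_id, spec, rtol, atol)
            r = _weighted_residual_vector(arrays, datasets)
            if not np.all(np.isfinite(r)):
                raise FloatingPointError
            return r
        except (IntegrationError, FloatingPointError, OverflowError):
            return np.full(n_res, np.sqrt(PENALTY / n_res))

    ls = least_squares(
        resid,
        best["theta"] / scale,
        bounds=(lo / scale, hi / scale),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=300 * spec.P,
    )
    theta_hat = ls.x * scale
    J_star = float(2 * ls.cost)
    if J_star > best["J"]:  # refinement should never worsen the best minimum
        theta_hat, J_star = best["theta"], best["J"]

    params, ics = spec.decode(theta_hat)
    frames = _residual_frames(theta_hat, datasets, model_id, spec, rtol, atol)
    jac = ls.jac / scale[np.newaxis, :]

    width = hi - lo
    bounds_hit = {}
    for name, v, a, b, w in zip(spec.free, theta_hat, lo, hi, width):
        if v - a < 1e-8 * w:
            bounds_hit[name] = "lower"
        elif b - v < 1e-8 * w:
            bounds_hit[name] = "upper"

    return FitResult(
        model_id=model_id,
        spec=spec,
        theta={n: float(v) for n, v in zip(spec.free, theta_hat)},
        params=params,
        ic_overrides=ics,
        J=J_star,
        residuals=frames,
        jacobian=jac,
        trace=trace,
        bounds_hit=bounds_hit,
    )


def _distinct_temperatures(datasets) -> list[float]:
    return sorted({ds.design.temperature for ds in datasets})


def _stage(datasets, model_id, free, fixed, x0_values, n_starts, seed, rtol, atol,
           bounds=None, nm_maxiter=None):
    spec = ParameterSpec(
        model_id=model_id,
        free=list(free),
        bounds=bounds or default_bounds({n: x0_values[n] for n in free}),
        fixed=dict(fixed),
    )
    return multi_start_fit(
        datasets, model_id, spec, n_starts=n_starts, seed=seed,
        x0=spec.x0_from(x0_values), rtol=rtol, atol=atol, nm_maxiter=nm_maxiter,
    )


def staged_fit_biomass(
    datasets,
    seed: int | None = None,
    theta0: Mapping[str, float] | None = None,
    n_starts: int = 1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    nm_maxiter: int | None = None,
) -> FitResult:
    """Three-stage identification of the biomass model across temperatures.

    (a) temperature-free fit (constant ``mu_max``/``r_vdk``), (b) the four
    temperature-law coefficients a-d with the stage-(a) stoichiometry
    pinned, (c) global refit of all ten parameters.  ``theta0`` provides
    the initial guesses (packaged defaults when omitted).  Datasets at a
    single temperature stop after stage (a) with a warning: the law
    coefficients are then structurally unidentifiable.
    """
    datasets = _as_list(datasets)
    theta0 = dict(theta0 or default_params("biomass"))
    stoich = ["kS", "kE", "S_min", "delta_X", "kV", "kCO2"]
    temps = _distinct_temperatures(datasets)
    t_ref = float(np.mean([ds.design.temperature for ds in datasets]))
    mu0, rv0 = temperature_laws("biomass", t_ref, theta0)

    x0_a = {**{n: theta0[n] for n in stoich}, "mu_max": mu0, "r_vdk": rv0}
    res_a = _stage(datasets, "biomass", list(x0_a), {}, x0_a,
                   n_starts, seed, rtol, atol, nm_maxiter=nm_maxiter)
    if len(temps) < 2:
        res_a.warnings.append(
            "single-temperature data: temperature-law coefficients are "
            "unidentifiable; returning the temperature-free stage-(a) fit"
        )
        res_a.stage_history = [res_a]
        return res_a

    fixed_b = {n: res_a.theta[n] for n in stoich}
    x0_b = {n: theta0[n] for n in ("a", "b", "c", "d")}
    res_b = _stage(datasets, "biomass", list(x0_b), fixed_b, x0_b,
                   n_starts, seed, rtol, atol, nm_maxiter=nm_maxiter)

    x0_c = {**fixed_b, **res_b.theta}
    res_c = _stage(datasets, "biomass", PARAM_NAMES["biomass"], {}, x0_c,
                   n_starts, seed, rtol, atol, nm_maxiter=nm_maxiter)
    res_c.stage_history = [res_a, res_b, res_c]
    return res_c


def staged_fit_co2(
    datasets,
    seed: int | None = None,
    theta0: Mapping[str, float] | None = None,
    KS_init: float = 10.0,
    n_starts: int = 1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    nm_maxiter: int | None = None,
) -> FitResult:
    """Four-stage identification of the CO2 model across temperatures.

    (a) temperature-free fit with KS pinned at the arbitrary ``KS_init``
    (its practical identifiability is poor), (b) KS alone, (c) the five
    temperature-law coefficients a-e, (d) global refit of all ten
    parameters.
    """
    datasets = _as_list(datasets)
    if KS_init <= 0:
        raise ValueError("KS_init must be > 0")
    theta0 = dict(theta0 or default_params("co2"))
    stoich = ["kS", "kE", "Cp_max", "kV"]
    temps = _distinct_temperatures(datasets)
    t_ref = float(np.mean([ds.design.temperature for ds in datasets]))
    mu0, rv0 = temperature_laws("co2", t_ref, theta0)

    x0_a = {**{n: theta0[n] for n in stoich}, "mu_max": mu0, "r_vdk": rv0}
    res_a = _stage(datasets, "co2", list(x0_a), {"KS": KS_init}, x0_a,
                   n_starts, seed, rtol, atol, nm_maxiter=nm_maxiter)
    if len(temps) < 2:
        res_a.warnings.append(
            "single-temperature data: temperature-law coefficients are "
            "unidentifiable; returning the temperature-free stage-(a) fit"
        )
        res_a.stage_history = [res_a]
        return res_a

    fixed_b = {n: res_a.theta[n] for n in stoich}
    fixed_b.update({"mu_max": res_a.theta["mu_max"], "r_vdk": res_a.theta["r_vdk"]})
    res_b = _stage(datasets, "co2", ["KS"], fixed_b, {"KS": KS_init},
                   n_starts, seed, rtol, atol, nm_maxiter=nm_maxiter)

    fixed_c = {n: res_a.theta[n] for n in stoich}
    fixed_c["KS"] = res_b.theta["KS"]
    x0_c = {n: theta0[n] for n in ("a", "b", "c", "d", "e")}
    res_c = _stage(datasets, "co2", list(x0_c), fixed_c, x0_c,
                   n_starts, seed, rtol, atol, nm_maxiter=nm_maxiter)

    x0_d = {**fixed_c, **res_c.theta}
    res_d = _stage(datasets, "co2", PARAM_NAMES["co2"], {}, x0_d,
                   n_starts, seed, rtol, atol, nm_maxiter=nm_maxiter)
    res_d.stage_history = [res_a, res_b, res_c, res_d]
    return res_d


def fit_initial_conditions(
    dataset: MeasurementSet,
    model_id: str,
    fixed_params: Mapping[str, float],
    seed: int | None = None,
    ic_names: Sequence[str] | None = None,
    n_starts: int = 1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Estimate only one experiment's initial state, parameters held fixed.

    This is the cross-validation protocol: the identified parameters are
    frozen and the held-out batch is predicted after re-estimating its
    starting point (which is itself corrupted by measurement noise in real
    campaigns).  Default free entries: ``X0, S0`` (biomass model) or
    ``CO2_0, S0`` (CO2 model).
    """
    if ic_names is None:
        ic_names = ("X0", "S0") if model_id == "biomass" else ("CO2_0", "S0")
    bad = [n for n in ic_names if n not in IC_STATE_NAMES[model_id]]
    if bad:
        raise ValueError(f"unknown initial-state name(s) {bad} for model {model_id!r}")
    design = dataset.design
    free = [_ic_name(design.id, n) for n in ic_names]
    bounds = {_ic_name(design.id, n): _IC_DEFAULT_BOUNDS[n] for n in ic_names}
    spec = ParameterSpec(model_id, free, bounds, fixed=dict(fixed_params))
    defaults = {
        "X0": design.X0, "S0": design.S0, "E0": max(design.E0, 1e-3),
        "CO2_0": design.CO2_0 if design.CO2_0 else 0.1,
        "VDK0": max(design.VDK0, 1e-3),
    }
    x0 = np.array([defaults[n] for n in ic_names])
    result = multi_start_fit(
        dataset, model_id, spec, n_starts=n_starts, seed=seed, x0=x0,
        rtol=rtol, atol=atol,
    )
    n_data = int(np.isfinite(dataset.data.to_numpy(dtype=float)).sum())
    if n_data < len(free):
        result.warnings.append(
            f"underdetermined: {len(free)} free initial conditions but only "
            f"{n_data} observations"
        )
    return result
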