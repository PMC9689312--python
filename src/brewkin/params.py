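"""Parameter containers and temperature laws for the two fermentation models.

Two batch ale-fermentation models are supported:

``"biomass"``
    Five dynamic states (biomass X, sugar S, ethanol E, cumulative CO2,
    vicinal diketones VDK) driven by a Droop-type growth rate that switches
    off when sugar reaches a threshold ``S_min``.

``"co2"``
    Two dynamic states (cumulative CO2 and VDK); sugar and ethanol are
    algebraic functions of CO2.  Growth is Monod-in-sugar times a logistic
    factor with carrying capacity ``Cp_max * S0``.

Both models make the maximum specific rate ``mu_max`` and the VDK reduction
rate ``r_vdk`` temperature dependent.  Temperatures are in degrees Celsius
throughout (the quadratic VDK law of the CO2 model carries coefficients in
degC^-2 h^-1, which pins the unit).  The calibrated range is 17-28 degC;
evaluation outside it is allowed but flagged.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import yaml

__all__ = [
    "BiomassParams",
    "CO2Params",
    "MODEL_IDS",
    "MODEL_STATES",
    "MODEL_VARIABLES",
    "PARAM_NAMES",
    "CALIBRATED_T_RANGE",
    "default_params",
    "temperature_laws",
    "as_dict",
]

MODEL_IDS = ("biomass", "co2")

#: dynamic states, in state-vector order
MODEL_STATES = {
    "biomass": ("X", "S", "E", "CO2", "VDK"),
    "co2": ("CO2", "VDK"),
}

#: observable variables (dynamic states plus algebraic outputs)
MODEL_VARIABLES = {
    "biomass": ("X", "S", "E", "CO2", "VDK"),
    "co2": ("CO2", "S", "E", "VDK"),
}

CALIBRATED_T_RANGE = (17.0, 28.0)


@dataclass
class BiomassParams:
    """Parameters of the biomass-based model.

    Yield coefficients are expressed per gram of biomass produced; the
    settling rate ``delta_X`` removes biomass from suspension without
    consuming sugar.  ``a, b`` and ``c, d`` are the coefficients of the
    logarithmic temperature laws ``mu_max = a*ln(T) + b`` and
    ``r_vdk = c*ln(T) + d``.
    """

    kS: float       # gS / gX
    kE: float       # gE / gX
    S_min: float    # g/L
    delta_X: float  # 1/h
    kV: float       # ppm / gX
    kCO2: float     # L / gX
    a: float        # 1/h
    b: float        # 1/h
    c: float        # 1/h
    d: float        # 1/h

    def __post_init__(self) -> None:
        for name in ("kS", "kE", "S_min", "kV", "kCO2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.delta_X < 0:
            raise ValueError(f"delta_X must be >= 0, got {self.delta_X}")


@dataclass
class CO2Params:
    """Parameters of the CO2-based model.

    Yields are per litre of CO2 evolved.  ``Cp_max`` sets the logistic
    carrying capacity ``Cp_max * S0``; the product ``kS * Cp_max`` must stay
    below 1 so that residual sugar ``S0 * (1 - kS*Cp_max)`` is positive.
    ``mu_max = a*ln(T) + b`` and ``r_vdk = c*T^2 + d*T + e`` with T in degC.
    """

    kS: float      # gS / L CO2
    kE: float      # gE / L CO2
    KS: float      # g/L
    Cp_max: float  # L / g
    kV: float      # ppm / L CO2
    a: float       # 1/h
    b: float       # 1/h
    c: float       # 1/(degC^2 h)
    d: float       # 1/(degC h)
    e: float       # 1/h

    def __post_init__(self) -> None:
        for name in ("kS", "kE", "KS", "Cp_max", "kV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.kS * self.Cp_max >= 1:
            raise ValueError(
                f"kS*Cp_max = {self.kS * self.Cp_max:.3f} >= 1: residual sugar "
                "would go negative before CO2 reaches its carrying capacity"
            )


PARAM_NAMES = {
    "biomass": tuple(f.name for f in dataclasses.fields(BiomassParams)),
    "co2": tuple(f.name for f in dataclasses.fields(CO2Params)),
}

_PARAM_CLS = {"biomass": BiomassParams, "co2": CO2Params}
_PARAM_FILE = {"biomass": "biomass_params.yaml", "co2": "co2_params.yaml"}


def _check_model_id(model_id: str) -> None:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def as_dict(params) -> dict:
    """Return a flat ``name -> value`` mapping for dataclass or mapping input."""
    if dataclasses.is_dataclass(params):
        return dataclasses.asdict(params)
    return dict(params)


def default_params(model_id: str, as_dataclass: bool = False):
    """Load the packaged default parameter set for ``model_id``.

    Returns a plain dict by default (the form the estimation layer works
    with), or the validated dataclass when ``as_dataclass`` is true.
    """
    _check_model_id(model_id)
    ref = importlib.resources.files("brewkin.data") / _PARAM_FILE[model_id]
    values = yaml.safe_load(ref.read_text())
    values = {k: float(v) for k, v in values.items()}
    if as_dataclass:
        return _PARAM_CLS[model_id](**values)
    return values


def temperature_laws(model_id: str, T: float, params) -> tuple[float, float]:
    """Evaluate ``(mu_max, r_vdk)`` at temperature ``T`` (degC).

    The biomass model uses logarithmic laws for both rates; the CO2 model
    uses a logarithmic law for ``mu_max`` and a quadratic in T for
    ``r_vdk``.  If ``params`` carries explicit ``mu_max`` / ``r_vdk``
    entries (the temperature-free parameterization used by the first stage
    of the staged fits) those constants take precedence.

    Raises ``ValueError`` for T <= 0; warns if an evaluated rate is
    negative, which signals extrapolation outside the calibrated 17-28 degC
    range.
    """
    _check_model_id(model_id)
    if T <= 0:
        raise ValueError(f"temperature must be positive (degC), got {T}")
    p = as_dict(params)
    if "mu_max" in p or "r_vdk" in p:
        mu_max = float(p["mu_max"])
        r_vdk = float(p["r_vdk"])
    elif model_id == "biomass":
        mu_max = p["a"] * math.log(T) + p["b"]
        r_vdk = p["c"] * math.log(T) + p["d"]
    else:
        mu_max = p["a"] * math.log(T) + p["b"]
        r_vdk = p["c"] * T**2 + p["d"] * T + p["e"]
    if mu_max < 0 or r_vdk < 0:
        warnings.warn(
            f"negative rate at T={T} degC (mu_max={mu_max:.4g}, r_vdk={r_vdk:.4g}): "
            f"model extrapolated outside the calibrated range {CALIBRATED_T_RANGE}",
            RuntimeWarning,
            stacklevel=2,
        )
    return mu_max, r_vdk
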