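"""Kinetic rate laws and ODE right-hand sides of the two fermentation models.

Biomass model (states X, S, E, CO2, VDK)::

    dX/dt   = (mu_X - delta_X) * X
    dS/dt   = -kS   * mu_X * X
    dE/dt   = +kE   * mu_X * X
    dCO2/dt = +kCO2 * mu_X * X
    dVDK/dt = kV * mu_X * X - r_vdk * VDK

with the Droop-type specific growth rate
``mu_X = mu_max * max(0, 1 - S_min/S)``: growth stops smoothly when sugar
falls to the threshold ``S_min``, which reproduces the residual sugar
observed at the end of real batches.  CO2 is a product of the overall
fermentation reaction, so its yield term enters with a positive sign.

CO2 model (states CO2, VDK; S and E algebraic)::

    dCO2/dt = mu_X * CO2,   mu_X = mu_max * S/(KS+S) * (1 - CO2/(Cp_max*S0))
    S = S0 - kS*CO2,        E = E0 + kE*CO2
    dVDK/dt = kV * mu_X * CO2 - r_vdk * VDK

The logistic factor gives the sigmoidal CO2 evolution with carrying
capacity ``Cp_max * S0``; CO2(0) must be strictly positive for fermentation
to start.
"""

from __future__ import annotations

import numpy as np

from .params import as_dict, temperature_laws

__all__ = ["mu_biomass", "mu_co2", "biomass_rhs", "co2_rhs", "co2_algebraic", "make_rhs"]


def mu_biomass(S, mu_max, S_min):
    """Droop-type specific growth rate ``mu_max * max(0, 1 - S_min/S)`` (1/h).

    Continuous in S, exactly zero for ``S <= S_min``; vectorized in S.
    """
    S = np.asarray(S, dtype=float)
    safe_S = np.maximum(S, 1e-300)
    rate = mu_max * np.maximum(0.0, 1.0 - S_min / safe_S)
    return rate if rate.ndim else float(rate)


def mu_co2(S, CO2, mu_max, KS, Cp_max, S0):
    """Monod-times-logistic specific CO2 production rate (1/h).

    ``mu_max * S/(KS+S) * (1 - CO2/(Cp_max*S0))``.  Sugar is clipped at 0 in
    the Monod factor so that off-manifold excursions during optimization
    (where ``S0 - kS*CO2`` may transiently go negative) stay well defined.
    The logistic factor is allowed to go negative beyond the carrying
    capacity, which pulls overshoots back.
    """
    S = np.asarray(S, dtype=float)
    CO2 = np.asarray(CO2, dtype=float)
    Sp = np.maximum(S, 0.0)
    rate = mu_max * (Sp / (KS + Sp)) * (1.0 - CO2 / (Cp_max * S0))
    return rate if rate.ndim else float(rate)


def biomass_rhs(t, state, params, T):
    """Right-hand side of the biomass model; ``state = [X, S, E, CO2, VDK]``."""
    p = as_dict(params)
    X, S, E, CO2, VDK = state
    mu_max, r_vdk = temperature_laws("biomass", T, p)
    mu = mu_biomass(S, mu_max, p["S_min"])
    growth = mu * X
    return np.array(
        [
            growth - p["delta_X"] * X,
            -p["kS"] * growth,
            p["kE"] * growth,
            p["kCO2"] * growth,
            p["kV"] * growth - r_vdk * VDK,
        ]
    )


def co2_algebraic(CO2, params, S0, E0=0.0):
    """Algebraic sugar and ethanol of the CO2 model: ``(S, E)`` from CO2."""
    p = as_dict(params)
    CO2 = np.asarray(CO2, dtype=float)
    S = S0 - p["kS"] * CO2
    E = E0 + p["kE"] * CO2
    if S.ndim:
        return S, E
    return float(S), float(E)


def co2_rhs(t, state, params, T, S0, E0=0.0):
    """Right-hand side of the CO2 model; ``state = [CO2, VDK]``."""
    p = as_dict(params)
    CO2, VDK = state
    mu_max, r_vdk = temperature_laws("co2", T, p)
    S, _ = co2_algebraic(CO2, p, S0, E0)
    mu = mu_co2(S, CO2, mu_max, p["KS"], p["Cp_max"], S0)
    return np.array([mu * CO2, p["kV"] * mu * CO2 - r_vdk * VDK])


def make_rhs(model_id, params, T, S0=None, E0=0.0):
    """Build a scalar fast-path RHS closure for the integrator.

    Hoists the temperature-law evaluation and parameter lookups out of the
    solver loop; numerically identical to :func:`biomass_rhs` /
    :func:`co2_rhs`.
    """
    p = as_dict(params)
    mu_max, r_vdk = temperature_laws(model_id, T, p)
    if model_id == "biomass":
        kS, kE, kCO2, kV = p["kS"], p["kE"], p["kCO2"], p["kV"]
        S_min, delta_X = p["S_min"], p["delta_X"]

        def rhs(t, y):
            X, S, E, CO2, VDK = y
            mu = mu_max * (1.0 - S_min / S) if S > S_min else 0.0
            g = mu * X
            return (g - delta_X * X, -kS * g, kE * g, kCO2 * g,
                    kV * g - r_vdk * VDK)

        return rhs

    kS, kV, KS, cap = p["kS"], p["kV"], p["KS"], p["Cp_max"] * S0

    def rhs(t, y):
        CO2, VDK = y
        S = S0 - kS * CO2
        if S < 0.0:
            S = 0.0
        g = mu_max * (S / (KS + S)) * (1.0 - CO2 / cap) * CO2
        return (g, kV * g - r_vdk * VDK)

    return rhs
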