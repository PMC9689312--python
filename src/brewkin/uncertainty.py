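"""Fisher-information uncertainty quantification for WLS parameter estimates.

From the output sensitivities ``y_theta`` at the optimum, the chain is:

    eps^2_hat = J* / (M*N - P)             a-posteriori relative error
    Omega_hat = eps^2_hat * W              measurement error covariance
    FIM       = sum_i y_theta(t_i)^T Omega_hat^-1 y_theta(t_i)
    Sigma_hat = FIM^-1                     Cramer-Rao covariance bound
    CV_i      = 100 * sqrt(Sigma_ii) / |theta_i|   (percent)

Sensitivities are computed by central finite differences on top of the
tightly-tolerated integrator.  An ill-conditioned FIM is a practical
identifiability warning: it is then pseudo-inverted and flagged rather
than silently inverted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimate import FitResult, ParameterSpec, _apply_ics, predict_outputs, weight_matrix
from .simulate import IntegrationError

__all__ = [
    "UncertaintyReport",
    "sensitivities",
    "epsilon_hat2",
    "fim_and_covariance",
    "coefficients_of_variation",
    "error_bars",
    "uncertainty_report",
]

#: condition number above which the FIM is pseudo-inverted and flagged
COND_LIMIT = 1e10


@dataclass
class UncertaintyReport:
    """Full uncertainty summary of one fit."""

    parameter_names: list[str]
    theta: np.ndarray
    sensitivity_stacks: list[np.ndarray]   # per dataset: (M, N, P)
    eps2: float
    fim: np.ndarray
    covariance: np.ndarray
    sigma: np.ndarray
    cv_percent: np.ndarray
    error_bars_95: list[dict]              # per dataset: variable -> half-width
    condition_number: float
    pseudo_inverse_used: bool

    def summary_table(self) -> str:
        """Human-readable parameter/value/CV table."""
        lines = [f"{'parameter':<12}{'estimate':>14}{'CV (%)':>10}"]
        for name, v, cv in zip(self.parameter_names, self.theta, self.cv_percent):
            cv_s = f"{cv:.1f}" if np.isfinite(cv) else "n/a"
            lines.append(f"{name:<12}{v:>14.4g}{cv_s:>10}")
        return "\n".join(lines)


def _model_outputs(theta, dataset, model_id, spec, rtol, atol):
    params, ics = spec.decode(theta)
    design = _apply_ics(dataset.design, model_id, ics.get(dataset.design.id, {}))
    return predict_outputs(model_id, params, design, dataset.times,
                           dataset.variables, rtol, atol)


def sensitivities(
    theta_hat,
    datasets,
    model_id: str,
    spec: ParameterSpec,
    rel_step: float = 1e-5,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> list[np.ndarray]:
    """Output sensitivities d y_model / d theta at every sample time.

    Central finite differences with relative step ``rel_step`` per free
    parameter; a failed perturbed integration degrades to a one-sided
    difference with a warning.  Returns one array of shape ``(M, N, P)``
    per dataset.
    """
    from .estimate import _as_list

    datasets = _as_list(datasets)
    theta_hat = np.asarray(theta_hat, dtype=float)
    base = [_model_outputs(theta_hat, ds, model_id, spec, rtol, atol) for ds in datasets]
    stacks = [np.zeros(b.shape + (spec.P,)) for b in base]
    for k in range(spec.P):
        h = rel_step * max(abs(theta_hat[k]), 1e-8)
        up, down = theta_hat.copy(), theta_hat.copy()
        up[k] += h
        down[k] -= h
        for i, ds in enumerate(datasets):
            try:
                y_up = _model_outputs(up, ds, model_id, spec, rtol, atol)
                y_dn = _model_outputs(down, ds, model_id, spec, rtol, atol)
                stacks[i][..., k] = (y_up - y_dn) / (2 * h)
            except IntegrationError:
                warnings.warn(
                    f"central difference failed for {spec.free[k]}; using a "
                    "one-sided difference",
                    RuntimeWarning,
                    stacklevel=2,
                )
                try:
                    y_up = _model_outputs(up, ds, model_id, spec, rtol, atol)
                    stacks[i][..., k] = (y_up - base[i]) / h
                except IntegrationError:
                    y_dn = _model_outputs(down, ds, model_id, spec, rtol, atol)
                    stacks[i][..., k] = (base[i] - y_dn) / h
    return stacks


def epsilon_hat2(J_star: float, M_total: int, N: int, P: int) -> float:
    """A-posteriori relative measurement error estimate ``J*/(M*N - P)``.

    ``M_total`` is the pooled sample count across experiments and ``N`` the
    number of observed variables (pass the total data count with ``N=1``
    when experiments observe different variable sets).
    """
    dof = M_total * N - P
    if dof <= 0:
        raise ValueError(f"M*N = {M_total * N} must exceed P = {P}")
    if J_star < 0:
        raise ValueError("J* must be >= 0")
    return J_star / dof


def fim_and_covariance(sens_stacks, W, eps2: float):
    """Fisher Information Matrix and Cramer-Rao covariance bound.

    ``FIM = sum_i y_theta(t_i)^T (eps2*W)^-1 y_theta(t_i)`` pooled over
    datasets; ``Sigma = FIM^-1``.  Accepts a single ``(M, N, P)`` stack
    with its weight matrix or lists of both.  Returns
    ``(FIM, Sigma, info)`` where ``info`` reports the condition number and
    whether a pseudo-inverse was required (a practical-identifiability
    red flag).
    """
    if isinstance(sens_stacks, np.ndarray):
        sens_stacks, W = [sens_stacks], [W]
    if eps2 < 0:
        raise ValueError("eps2 must be >= 0")
    P = sens_stacks[0].shape[-1]
    # eps2 factors out of the FIM as 1/eps2: accumulate the unit-noise
    # information so the eps2 = 0 (perfect fit) limit stays well defined
    funit = np.zeros((P, P))
    for stack, w in zip(sens_stacks, W):
        w_inv = 1.0 / np.diag(w)
        for i in range(stack.shape[0]):
            yt = stack[i]  # (N, P)
            funit += yt.T @ (w_inv[:, None] * yt)
    funit = 0.5 * (funit + funit.T)  # enforce exact symmetry
    sv = np.linalg.svd(funit, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    pseudo = not np.isfinite(cond) or cond > COND_LIMIT
    if pseudo:
        warnings.warn(
            f"FIM condition number {cond:.2e} exceeds {COND_LIMIT:.0e}: "
            "using a pseudo-inverse; some parameters are practically "
            "unidentifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    info = {"condition_number": cond, "pseudo_inverse": pseudo}
    if eps2 == 0.0:
        warnings.warn(
            "eps2 = 0 (perfect fit): covariance is the zero-noise limit",
            RuntimeWarning,
            stacklevel=2,
        )
        fim = np.where(funit != 0.0, np.sign(funit) * np.inf, 0.0)
        return fim, np.zeros((P, P)), info
    fim = funit / eps2
    if pseudo:
        cov = eps2 * np.linalg.pinv(funit, rcond=1 / COND_LIMIT)
    else:
        cov = eps2 * np.linalg.inv(funit)
    return fim, cov, info


def coefficients_of_variation(covariance: np.ndarray, theta_hat) -> np.ndarray:
    """Per-parameter CV in percent, ``100*sqrt(Sigma_ii)/|theta_i|``.

    Undefined (NaN, with a warning) for parameters estimated at exactly 0.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    sigma = np.sqrt(np.maximum(np.diag(covariance), 0.0))
    cv = np.full_like(theta_hat, np.nan)
    nonzero = theta_hat != 0
    cv[nonzero] = 100.0 * sigma[nonzero] / np.abs(theta_hat[nonzero])
    if not nonzero.all():
        warnings.warn("CV undefined for parameter(s) estimated at 0",
                      RuntimeWarning, stacklevel=2)
    return cv


def error_bars(W: np.ndarray, eps2: float) -> np.ndarray:
    """95% half-widths per variable: ``1.96*sqrt(eps2*W_jj)``.

    Constant per variable, as implied by the relative-error model behind W.
    """
    if eps2 < 0:
        raise ValueError("eps2 must be >= 0")
    return 1.96 * np.sqrt(eps2 * np.diag(W))


def uncertainty_report(
    fit: FitResult,
    datasets,
    rel_step: float = 1e-5,
) -> UncertaintyReport:
    """Assemble the full uncertainty chain for a finished fit."""
    from .estimate import _as_list

    datasets = _as_list(datasets)
    theta = fit.theta_vector
    stacks = sensitivities(theta, datasets, fit.model_id, fit.spec, rel_step)
    W = [weight_matrix(ds) for ds in datasets]
    n_data = sum(int(np.isfinite(ds.data.to_numpy(dtype=float)).sum()) for ds in datasets)
    eps2 = epsilon_hat2(fit.J, n_data, 1, fit.spec.P)
    fim, cov, info = fim_and_covariance(stacks, W, eps2)
    sigma = np.sqrt(np.maximum(np.diag(cov), 0.0))
    cv = coefficients_of_variation(cov, theta)
    bars = []
    for ds, w in zip(datasets, W):
        half = error_bars(w, eps2)
        bars.append(dict(zip(ds.variables, half)))
    return UncertaintyReport(
        parameter_names=list(fit.spec.free),
        theta=theta,
        sensitivity_stacks=stacks,
        eps2=eps2,
        fim=fim,
        covariance=cov,
        sigma=sigma,
        cv_percent=cv,
        error_bars_95=bars,
        condition_number=info["condition_number"],
        pseudo_inverse_used=info["pseudo_inverse"],
    )
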