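# Methods

This note records the mathematical models, the numerical choices behind the
`brewkin` library, and their known limitations. Symbols follow the source
code (`brewkin.params.PARAM_NAMES`).

## Models

Both models describe an isothermal batch ale fermentation at temperature
`T` (°C), calibrated over 17–28 °C.

### Biomass model

Five states — biomass `X` (g/L), sugar `S` (g/L), ethanol `E` (g/L),
cumulative CO2 (L), vicinal diketones `VDK` (ppm):

```
mu_X    = mu_max(T) * max(0, 1 - S_min/S)
dX/dt   = (mu_X - delta_X) * X
dS/dt   = -kS   * mu_X * X
dE/dt   = +kE   * mu_X * X
dCO2/dt = +kCO2 * mu_X * X
dVDK/dt = kV * mu_X * X - r_vdk(T) * VDK
```

The Droop-type factor `max(0, 1 - S_min/S)` stops growth smoothly at the
residual-sugar threshold `S_min`; `delta_X` is a slow settling/decay rate.
All three product yields are proportional to the same growth flux
`mu_X * X`, so the model has two exact first integrals,
`kE*S + kS*E` and `kCO2*S + kS*CO2`, which the test suite uses as
integrator oracles. The CO2 yield enters with a **positive** sign: CO2 is
a product of the fermentation reaction, and a negative yield with
`kCO2 > 0` would produce negative cumulative CO2.

Temperature laws: `mu_max = a*ln(T) + b`, `r_vdk = c*ln(T) + d`.

### CO2 model

Two dynamic states (CO2, VDK) with sugar and ethanol recovered
algebraically from the CO2 evolved:

```
mu_X    = mu_max(T) * S/(KS + S) * (1 - CO2/(Cp_max*S0))
dCO2/dt = mu_X * CO2
dVDK/dt = kV * mu_X * CO2 - r_vdk(T) * VDK
S       = S0 - kS*CO2
E       = E0 + kE*CO2
```

A Monod factor in the (algebraic) sugar times a logistic brake with
carrying capacity `Cp_max * S0` (litres of CO2 per batch). `CO2(0)` must
be strictly positive for fermentation to start; the default initial value
is 0.1 L. Temperature laws: `mu_max = a*ln(T) + b`,
`r_vdk = c*T^2 + d*T + e`.

Both `temperature_laws` implementations accept constant overrides
(`mu_max`, `r_vdk` keys in the parameter dict), which is how the
temperature-free stages of the staged fits and the identifiability
augmentation are expressed.

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA, `rtol=1e-8 / atol=1e-10` by
default. The `Trajectory` object carries the dense output for
interpolation at arbitrary observation times. The fitting fast path
(`predict_outputs`) evaluates the same interpolant via `t_eval` without
building tables; the two paths agree bit-for-bit because `solve_ivp`
serves both from the identical step interpolants. Reported states are
clipped at zero (the clip is cosmetic: unclipped values only ever
undershoot by integrator noise). First integrals are conserved to better
than 1e-6 relative over a full batch (tested).

## Synthetic data

The four batch designs (duration, temperature, S0, X0) are the
experimental campaign the models were built for: (72 h, 19 °C, 88, 0.705),
(54 h, 19 °C, 72, 0.529), (96 h, 21 °C, 75, 0.705),
(72 h, 28 °C, 81, 0.705). Sampling uses a dense early grid (2.5 h up to
36 h) and an 8 h late grid, final time always included. Noise is additive
Gaussian per variable with standard deviation `sigma_rel * max_t y(t)`
(relative to the trajectory maximum, matching the WLS weighting), then
truncated at zero. Truncation biases samples whose true value is within
~2–3 sd of zero (early ethanol, early VDK); tests that verify the noise
law therefore use late samples.

Batches 2–4 (two temperatures would not identify a 2-coefficient law, so
the three-temperature partition 19/21/28 °C is used for fitting) are the
training partition; batch 1 is held out for cross-validation.

## Estimation

WLS objective `J = sum r^T W^-1 r` pooled over experiments, `W` diagonal
with the squares of each variable's measured maximum (relative-error
model). Missing cells (NaN) are skipped. Integration failures return a
penalty of 1e6 so derivative-free search continues.

Minimization is two-step: Nelder–Mead (bounded, adaptive for P > 4,
capped at 150·P evaluations) from one or more starts — the informed start
first, then log-uniform draws within bounds — followed by a
`least_squares` trust-region-reflective polish (`tol = 1e-12`) whose
residual Jacobian feeds the uncertainty analysis. Internally theta is
scaled by the magnitude of the first start so parameters spanning four
orders of magnitude share one simplex scale.

Staged recipes (temperature-dependent parameters cannot be identified in
one shot from a cold start):

* biomass — (a) all six stoichiometric/kinetic constants plus constant
  `mu_max`, `r_vdk`; (b) the law coefficients a–d with stage-(a) values
  pinned; (c) global refit of all ten parameters.
* CO2 — (a) constants with the weakly identifiable `KS` pinned at an
  arbitrary 10 g/L; (b) `KS` alone; (c) law coefficients a–e; (d) global
  refit.

Single-temperature data stops after stage (a) with a warning (the law
coefficients are then structurally unidentifiable). On noise-free data
from the training partition the staged fits recover every generating
parameter to machine precision from 1.5x-truth starts (acceptance tests 3
and 4).

Cross-validation refits only the held-out batch's initial conditions
(`fit_initial_conditions`), parameters frozen — the protocol for a batch
whose starting point is itself measured with error.

## Uncertainty

A-posteriori error `eps2 = J*/(M·N − P)` with `M·N` the pooled finite
observation count; measurement covariance `Omega = eps2 * W`; Fisher
information `FIM = sum_i y_theta(t_i)^T Omega^-1 y_theta(t_i)` summed over
all samples of all experiments; Cramér–Rao bound `Sigma = FIM^-1`;
`CV_i = 100*sqrt(Sigma_ii)/|theta_i|`; 95% error bars per variable
`1.96*sqrt(eps2*W_jj)`. Sensitivities `y_theta` by central finite
differences (relative step 1e-5) over tightly tolerated integrations
(`rtol=1e-10`). A FIM condition number above 1e10 switches to a
pseudo-inverse with a warning — a practical-identifiability red flag. The
`eps2 = 0` limit (exact fit) returns zero covariance rather than NaNs.
The reported sigmas are frequentist-calibrated: over 20 noisy replicates,
every parameter falls within 3 reported sd of truth in ≥90% of replicates
(acceptance test 6).

## Observability and identifiability

Local observability is decided by the rank of the empirical observability
matrix: the finite-difference Jacobian of the output trajectory over a
24 h window (15 times) with respect to the initial state, integrated at
`rtol=1e-11`. Columns are scaled by the magnitude of the perturbed
component (relative perturbations) and rows by each output block's
magnitude; singular values below `1e-5 * s_max` count as zero. The row
space of this Jacobian coincides locally with the span of the gradients of
the outputs' Lie derivatives, so the rank condition is the standard
nonlinear observability rank test evaluated without nested symbolic or
nested-FD differentiation (one FD level on a tightly tolerated integration
is numerically far better conditioned than k nested FD levels). The test
repeats at 3 random generic mid-fermentation points; a non-unanimous rank
is reported as indeterminate. Per-state flags come from the numerical
null space: a state is lost when a null-space vector has a component on
it.

Identifiability mode augments the state with the batch-level parameters
as constant states — including `mu_max` and `r_vdk` directly, since an
isothermal batch cannot separate temperature-law coefficients.

Caveat: for the CO2 model the ethanol yield `kE` enters only the algebraic
ethanol output, so identifiability of the full parameter set requires
measuring the algebraic variables (S, E) too, not just the dynamic states
(CO2, VDK).

## Limitations

* Both models are isothermal-batch models; the temperature laws are fitted
  over 17–28 °C and `mu_max(T)` goes negative below ~9 °C (biomass) /
  ~16 °C (CO2 model) — extrapolation outside the calibrated range is
  unsupported and triggers a warning in `ExperimentDesign`.
* The observability verdicts are *local* (rank at generic points) and
  numerical; they cannot distinguish structural non-observability from
  pathological near-rank-deficiency closer than the SVD threshold.
* The Cramér–Rao CVs assume the relative-error noise model behind `W`;
  under misspecified noise they are only indicative.
* All empirical statements in this repository refer to synthetic data
  generated by the models themselves; no claims are made about real
  fermentation measurements.
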