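"""WLS objective, multi-start optimization, and staged/IC fitting."""

import numpy as np
import pandas as pd
import pytest

from brewkin import (
    fit_initial_conditions,
    make_dataset,
    multi_start_fit,
    objective,
    staged_fit_biomass,
    weight_matrix,
)
from brewkin.datasets import MeasurementSet
from brewkin.estimate import ParameterSpec, default_bounds
from brewkin.params import PARAM_NAMES


def _spec(model_id, truth, free=None):
    free = free or list(PARAM_NAMES[model_id])
    return ParameterSpec(
        model_id, free, default_bounds({n: truth[n] for n in free}),
        fixed={n: v for n, v in truth.items() if n not in free},
    )


class TestWeightMatrix:
    def test_squared_maxima_on_diagonal(self, biomass_clean):
        ds = biomass_clean[0]
        W = weight_matrix(ds)
        expected = ds.data.max().to_numpy() ** 2
        assert np.allclose(np.diag(W), expected)
        assert np.allclose(W - np.diag(np.diag(W)), 0.0)

    def test_hand_example(self, biomass_clean):
        ds = biomass_clean[0]
        toy = MeasurementSet(
            ds.model_id, ds.design,
            pd.DataFrame({"S": [2.0, 1.0], "E": [10.0, 4.0]}, index=[0.0, 5.0]),
        )
        assert np.allclose(np.diag(weight_matrix(toy)), [4.0, 100.0])

    def test_degenerate_variable_rejected(self, biomass_clean):
        ds = biomass_clean[0]
        toy = MeasurementSet(
            ds.model_id, ds.design,
            pd.DataFrame({"S": [0.0, 0.0], "E": [1.0, 2.0]}, index=[0.0, 5.0]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            weight_matrix(toy)


class TestObjective:
    def test_zero_at_generating_truth(self, biomass_truth, biomass_clean):
        spec = _spec("biomass", biomass_truth)
        J = objective(spec.x0_from(biomass_truth), biomass_clean, "biomass", spec)
        assert J == pytest.approx(0.0, abs=1e-10)

    def test_oracle_equivalence_scalar_loop(self, co2_truth, co2_clean):
        """Vectorized J agrees with a hand-coded scalar double loop to 1e-12."""
        ds = co2_clean[0]
        toy = MeasurementSet(
            ds.model_id, ds.design,
            ds.data.iloc[[2, 5, 9]][["CO2", "E"]] * [1.03, 0.95],
        )
        theta = {k: v * 1.1 for k, v in co2_truth.items()}
        spec = _spec("co2", co2_truth)
        J = objective(spec.x0_from(theta), toy, "co2", spec)

        from brewkin.estimate import predict_outputs
        pred = predict_outputs("co2", theta, toy.design, toy.times, ["CO2", "E"])
        maxima = [toy.data["CO2"].max(), toy.data["E"].max()]
        J_ref = 0.0
        for i in range(3):
            for j, v in enumerate(["CO2", "E"]):
                r = toy.data[v].iloc[i] - pred[i, j]
                J_ref += r**2 / maxima[j] ** 2
        assert J == pytest.approx(J_ref, abs=1e-12)

    def test_quadratic_in_residuals(self, biomass_truth, biomass_clean):
        """Doubling every residual (by moving the data) quadruples J.

        The perturbation is proportional to (max - prediction) per column, so
        the per-variable maxima — and hence W — are identical for both
        datasets and the scaling is exact.
        """
        spec = _spec("biomass", biomass_truth)
        theta = spec.x0_from(biomass_truth)
        from brewkin import integrate, observe
        ds = biomass_clean[0]
        traj = integrate("biomass", biomass_truth, ds.design)
        pred = observe(traj, ds.variables, ds.times)

        def with_residuals(k):
            data = pred + 0.02 * k * (pred.max() - pred)
            return MeasurementSet(ds.model_id, ds.design, data)

        J1 = objective(theta, with_residuals(1.0), "biomass", spec)
        J2 = objective(theta, with_residuals(2.0), "biomass", spec)
        assert J2 / J1 == pytest.approx(4.0, rel=1e-6)

    def test_invariant_under_experiment_reordering(self, biomass_truth, biomass_clean):
        spec = _spec("biomass", biomass_truth)
        theta = spec.x0_from(biomass_truth) * 1.2
        J_fwd = objective(theta, biomass_clean, "biomass", spec)
        J_rev = objective(theta, biomass_clean[::-1], "biomass", spec)
        assert J_fwd == pytest.approx(J_rev, rel=1e-14)

    def test_penalty_instead_of_raise_on_unintegrable_theta(self, co2_truth, co2_clean):
        spec = _spec("co2", co2_truth)
        theta = spec.x0_from(co2_truth)
        theta[spec.free.index("a")] = 141.0  # mu_max ~ 400/h: hopeless stiffness
        J = objective(theta, co2_clean, "co2", spec)
        assert np.isfinite(J)


class TestParameterSpec:
    def test_partition_must_cover_model(self, co2_truth):
        with pytest.raises(ValueError, match="cover"):
            ParameterSpec("co2", ["kS"], {"kS": (0.01, 10)}, fixed={"kE": 0.1})

    def test_constant_law_partition_accepted(self, co2_truth):
        fixed = {n: co2_truth[n] for n in ("kE", "KS", "Cp_max", "kV")}
        fixed.update({"mu_max": 0.26, "r_vdk": 0.02})
        spec = ParameterSpec("co2", ["kS"], {"kS": (0.01, 10)}, fixed=fixed)
        params, ics = spec.decode(np.array([0.372]))
        assert params["kS"] == 0.372 and not ics

    def test_ic_entries_decode_to_overrides(self, biomass_truth):
        spec = ParameterSpec(
            "biomass", ["kS", "ic:2:S0"],
            {"kS": (1, 100), "ic:2:S0": (10, 200)},
            fixed={n: v for n, v in biomass_truth.items() if n != "kS"},
        )
        params, ics = spec.decode(np.array([15.3, 72.5]))
        assert ics == {"2": {"S0": 72.5}}


class TestMultiStartFit:
    def test_recovers_perturbed_yields(self, co2_truth, co2_clean):
        """Noise-free two-parameter recovery from a 30%-off start."""
        spec = _spec("co2", co2_truth, free=["kE", "kV"])
        x0 = np.array([co2_truth["kE"] * 1.3, co2_truth["kV"] * 0.7])
        fit = multi_start_fit(co2_clean, "co2", spec, n_starts=1, seed=0, x0=x0)
        assert fit.theta["kE"] == pytest.approx(co2_truth["kE"], rel=1e-4)
        assert fit.theta["kV"] == pytest.approx(co2_truth["kV"], rel=1e-4)
        assert fit.J < 1e-10

    def test_start_at_truth_is_fixed_point(self, co2_truth, co2_clean):
        spec = _spec("co2", co2_truth, free=["kE", "kV"])
        x0 = spec.x0_from(co2_truth)
        fit = multi_start_fit(co2_clean, "co2", spec, n_starts=1, seed=0, x0=x0)
        assert fit.J == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.theta_vector, x0, rtol=1e-6)

    def test_seed_determinism(self, co2_truth, co2_clean):
        spec = _spec("co2", co2_truth, free=["kE", "kV"])
        fits = [
            multi_start_fit(co2_clean, "co2", spec, n_starts=3, seed=11,
                            nm_maxiter=60)
            for _ in range(2)
        ]
        assert np.allclose(fits[0].theta_vector, fits[1].theta_vector, rtol=0, atol=0)
        starts0 = [t["start"] for t in fits[0].trace]
        starts1 = [t["start"] for t in fits[1].trace]
        assert all(np.array_equal(a, b) for a, b in zip(starts0, starts1))

    def test_objective_never_worse_than_best_simplex_minimum(
            self, co2_truth, co2_clean):
        spec = _spec("co2", co2_truth, free=["kE", "kV"])
        fit = multi_start_fit(co2_clean, "co2", spec, n_starts=2, seed=3,
                              nm_maxiter=40)
        assert fit.J <= min(t["J"] for t in fit.trace) + 1e-15


class TestStagedFits:
    def test_single_temperature_stops_after_stage_a(self, biomass_truth, designs):
        ds = [make_dataset("biomass", biomass_truth, d, sigma_rel=0.0)
              for d in designs[:2]]  # both at 19 degC
        fit = staged_fit_biomass(ds, seed=0, nm_maxiter=50)
        assert len(fit.stage_history) == 1
        assert any("unidentifiable" in w for w in fit.warnings)
        assert "mu_max" in fit.theta and "a" not in fit.theta


class TestFitInitialConditions:
    def test_recovers_heldout_sugar_start(self, co2_truth, designs):
        """Cross-validation protocol: frozen parameters, design-1 data with
        S0 = 88 recovered from a deliberately wrong nominal start."""
        import dataclasses
        ds = make_dataset("co2", co2_truth, designs[0], sigma_rel=0.0)
        ds = MeasurementSet(
            "co2", dataclasses.replace(designs[0], S0=70.0, CO2_0=0.5),
            ds.data, provenance="synthetic",
        )
        fit = fit_initial_conditions(ds, "co2", co2_truth, seed=0)
        assert fit.theta[f"ic:1:S0"] == pytest.approx(88.0, rel=1e-3)
        assert fit.theta[f"ic:1:CO2_0"] == pytest.approx(0.1, rel=1e-2)

    def test_underdetermined_single_sample_flagged(self, co2_truth, co2_clean):
        ds = co2_clean[0]
        tiny = MeasurementSet("co2", ds.design, ds.data.iloc[[0]][["CO2"]])
        fit = fit_initial_conditions(tiny, "co2", co2_truth, seed=0,
                                     n_starts=1)
        assert any("underdetermined" in w for w in fit.warnings)
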