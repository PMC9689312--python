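"""Fisher-information uncertainty chain: eps2, FIM, covariance, CV, bars."""

import numpy as np
import pytest

from brewkin import (
    coefficients_of_variation,
    epsilon_hat2,
    error_bars,
    fim_and_covariance,
    multi_start_fit,
    sensitivities,
    uncertainty_report,
)
from brewkin.estimate import ParameterSpec, default_bounds


def _spec(model_id, truth, free):
    return ParameterSpec(
        model_id, list(free), default_bounds({n: truth[n] for n in free}),
        fixed={n: v for n, v in truth.items() if n not in free},
    )


class TestEpsilonHat2:
    def test_hand_value(self):
        assert epsilon_hat2(2.0, 25, 1, 5) == pytest.approx(0.1)
        assert epsilon_hat2(2.0, 5, 5, 5) == pytest.approx(0.1)

    def test_perfect_fit_gives_zero(self):
        assert epsilon_hat2(0.0, 30, 1, 3) == 0.0

    def test_no_degrees_of_freedom_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            epsilon_hat2(1.0, 5, 1, 5)
        with pytest.raises(ValueError):
            epsilon_hat2(-1.0, 30, 1, 3)


class TestFimAndCovariance:
    def test_identity_sensitivities(self):
        """y_theta = I at one sample with W = I, eps2 = 1 gives FIM = Sigma = I."""
        stack = np.eye(3)[None, :, :]  # (M=1, N=3, P=3)
        fim, cov, info = fim_and_covariance(stack, np.eye(3), 1.0)
        assert np.allclose(fim, np.eye(3))
        assert np.allclose(cov, np.eye(3))
        assert not info["pseudo_inverse"]

    def test_duplicating_data_halves_covariance(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(size=(4, 2, 3))
        W = np.diag([2.0, 5.0])
        fim1, cov1, _ = fim_and_covariance(stack, W, 0.3)
        fim2, cov2, _ = fim_and_covariance(
            np.concatenate([stack, stack]), W, 0.3)
        assert np.allclose(fim2, 2 * fim1)
        assert np.allclose(cov2, cov1 / 2)

    def test_eps2_scales_covariance_linearly(self):
        rng = np.random.default_rng(1)
        stack = rng.normal(size=(5, 2, 2))
        W = np.eye(2)
        _, cov1, _ = fim_and_covariance(stack, W, 0.1)
        _, cov2, _ = fim_and_covariance(stack, W, 0.2)
        assert np.allclose(cov2, 2 * cov1)

    def test_unidentifiable_product_flagged(self):
        """y = theta1*theta2*t: the two columns of y_theta are collinear, so
        the FIM is singular and only a pseudo-inverse is possible."""
        t = np.linspace(1, 5, 6)
        th1, th2 = 2.0, 3.0
        stack = np.stack([th2 * t, th1 * t], axis=1)[:, None, :]  # (6,1,2)
        with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
            fim, cov, info = fim_and_covariance(stack, np.eye(1), 1.0)
        assert info["pseudo_inverse"]
        assert np.linalg.matrix_rank(fim, tol=1e-8 * np.abs(fim).max()) == 1

    def test_multi_dataset_pooling(self):
        rng = np.random.default_rng(2)
        s1, s2 = rng.normal(size=(3, 2, 2)), rng.normal(size=(4, 2, 2))
        W = np.diag([1.0, 4.0])
        fim_a, _, _ = fim_and_covariance(s1, W, 1.0)
        fim_b, _, _ = fim_and_covariance(s2, W, 1.0)
        fim_ab, _, _ = fim_and_covariance([s1, s2], [W, W], 1.0)
        assert np.allclose(fim_ab, fim_a + fim_b)


class TestCvAndErrorBars:
    def test_cv_hand_values(self):
        cov = np.diag([0.25, 0.0])
        cv = coefficients_of_variation(cov, [10.0, 3.0])
        assert cv[0] == pytest.approx(5.0)
        assert cv[1] == pytest.approx(0.0)

    def test_cv_nan_for_zero_estimate(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            cv = coefficients_of_variation(np.eye(2), [1.0, 0.0])
        assert np.isnan(cv[1]) and cv[0] == pytest.approx(100.0)

    def test_error_bar_hand_value(self):
        # 1.96 * sqrt(0.01 * 4) = 0.392
        bars = error_bars(np.diag([4.0]), 0.01)
        assert bars[0] == pytest.approx(0.392)
        assert error_bars(np.diag([4.0, 9.0]), 0.0) == pytest.approx([0.0, 0.0])


class TestSensitivities:
    def test_structural_zero_kv_to_sugar(self, biomass_truth, biomass_clean):
        """VDK yield kV feeds no other state: dS/dkV and dE/dkV are exactly 0."""
        spec = _spec("biomass", biomass_truth, ["kV", "kE"])
        ds = biomass_clean[0]
        stacks = sensitivities(spec.x0_from(biomass_truth), [ds], "biomass", spec)
        j_s = ds.variables.index("S")
        j_e = ds.variables.index("E")
        k_kv = spec.free.index("kV")
        # zero up to finite-difference noise from the integrator tolerance
        assert np.allclose(stacks[0][:, j_s, k_kv], 0.0, atol=1e-6)
        assert np.allclose(stacks[0][:, j_e, k_kv], 0.0, atol=1e-6)

    def test_ethanol_sensitivity_closed_form(self, biomass_truth, biomass_clean):
        """E = E0 + kE*(integral of mu X) is linear in kE, so
        dE/dkE = (E - E0)/kE along the trajectory."""
        spec = _spec("biomass", biomass_truth, ["kE"])
        ds = biomass_clean[0]
        stacks = sensitivities(spec.x0_from(biomass_truth), [ds], "biomass", spec)
        j_e = ds.variables.index("E")
        E = ds.data["E"].to_numpy()
        expected = (E - ds.design.E0) / biomass_truth["kE"]
        assert np.allclose(stacks[0][:, j_e, 0], expected, rtol=1e-4, atol=1e-6)

    def test_step_halving_converges(self, co2_truth, co2_clean):
        spec = _spec("co2", co2_truth, ["kE", "Cp_max"])
        theta = spec.x0_from(co2_truth)
        ds = co2_clean[0]
        s1 = sensitivities(theta, [ds], "co2", spec, rel_step=1e-4)[0]
        s2 = sensitivities(theta, [ds], "co2", spec, rel_step=5e-5)[0]
        scale = np.abs(s1).max()
        assert np.allclose(s1, s2, atol=1e-5 * scale)


@pytest.fixture(scope="module")
def clean_fit_report(co2_truth, co2_clean):
    spec = _spec("co2", co2_truth, ["kE", "kV", "Cp_max"])
    fit = multi_start_fit(co2_clean, "co2", spec, n_starts=1, seed=0,
                          x0=spec.x0_from(co2_truth))
    return fit, uncertainty_report(fit, co2_clean)


class TestUncertaintyReport:
    def test_noise_free_fit_has_vanishing_uncertainty(self, clean_fit_report):
        fit, rep = clean_fit_report
        assert rep.eps2 < 1e-10
        assert np.all(rep.cv_percent < 1e-2)
        for bars in rep.error_bars_95:
            assert all(v < 1e-2 for v in bars.values())

    def test_report_is_consistent_with_primitives(self, clean_fit_report, co2_clean):
        """The assembled report equals the primitive chain recomputed by hand."""
        from brewkin import weight_matrix

        fit, rep = clean_fit_report
        n_data = sum(np.isfinite(ds.data.to_numpy()).sum() for ds in co2_clean)
        assert rep.eps2 == pytest.approx(
            epsilon_hat2(fit.J, int(n_data), 1, fit.spec.P))
        W = [weight_matrix(ds) for ds in co2_clean]
        fim, cov, _ = fim_and_covariance(rep.sensitivity_stacks, W, rep.eps2)
        assert np.allclose(fim, rep.fim)
        assert np.allclose(cov, rep.covariance)
        assert np.allclose(rep.sigma, np.sqrt(np.diag(cov)))
        assert "CV (%)" in rep.summary_table()
        assert rep.parameter_names == ["kE", "kV", "Cp_max"]
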