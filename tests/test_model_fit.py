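import numpy as np
import pytest

from fcsquant.correlator import CorrelationCurve
from fcsquant.model_fit import FitResult, fit_curve, model_g, two_stage_fit
from fcsquant.synthetic import generate_curve, make_lag_grid

from conftest import tau_from_d


class TestModelG:
    def test_amplitude_identity_one_component(self):
        assert model_g(0.0, n_molecules=10, tau_fast_s=1e-3) == pytest.approx(0.1)

    def test_value_at_tau1_closed_form(self):
        # one component, S=4, lag == tau1: (1/2N) * (1 + 1/16)^(-1/2)
        n = 7.0
        expected = 0.5 * (1 + 1 / 16) ** -0.5 / n
        assert model_g(1e-3, n_molecules=n, tau_fast_s=1e-3,
                       structural_parameter=4.0) == pytest.approx(expected, rel=1e-12)
        assert expected * n == pytest.approx(0.48507125007266594)

    def test_decays_to_offset(self):
        val = model_g(1e6, n_molecules=5, tau_fast_s=1e-3, offset=0.004)
        assert val == pytest.approx(0.004, abs=1e-8)

    def test_amplitude_with_triplet_and_offset(self):
        g0 = model_g(0.0, n_molecules=8, tau_fast_s=1e-3,
                     triplet_fraction=0.2, offset=0.01)
        assert g0 == pytest.approx((1 / 8) / 0.8 + 0.01, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_nonincreasing_without_offset(self, seed):
        rng = np.random.default_rng(seed)
        lags = np.geomspace(1e-7, 10, 2000)
        g = model_g(
            lags,
            n_molecules=rng.uniform(1, 100),
            frac_fast=rng.uniform(0, 1),
            tau_fast_s=10 ** rng.uniform(-5, -3),
            tau_slow_s=10 ** rng.uniform(-3, -1),
            triplet_fraction=rng.uniform(0, 0.5),
            tau_triplet_s=10 ** rng.uniform(-6, -4.5),
            structural_parameter=rng.uniform(1, 10),
        )
        assert np.all(np.diff(g) <= 1e-15)

    def test_component_relabelling_invariance(self):
        lags = np.geomspace(1e-6, 1, 50)
        a = model_g(lags, n_molecules=10, frac_fast=0.3, tau_fast_s=1e-3,
                    tau_slow_s=5e-2)
        b = model_g(lags, n_molecules=10, frac_fast=0.7, tau_fast_s=5e-2,
                    tau_slow_s=1e-3)
        np.testing.assert_allclose(a, b, rtol=1e-14)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            model_g(1e-3, n_molecules=10, tau_fast_s=1e-3, triplet_fraction=1.0)
        with pytest.raises(ValueError):
            model_g(1e-3, n_molecules=10, tau_fast_s=-1e-3)
        with pytest.raises(ValueError):
            model_g(1e-3, n_molecules=-1, tau_fast_s=1e-3)


class TestFitCurve:
    def test_noise_free_round_trip(self, lag_grid, two_component_params):
        curve = generate_curve(two_component_params, lag_grid, 0.0,
                               mean_rate_khz=100.0)
        fit = fit_curve(curve, components=2, fix_s=4.0)
        assert fit.ok
        p = two_component_params
        assert fit.n_molecules == pytest.approx(p["n_molecules"], rel=1e-4)
        assert fit.frac_fast == pytest.approx(p["frac_fast"], rel=1e-4)
        assert fit.tau_fast_s == pytest.approx(p["tau_fast_s"], rel=1e-4)
        assert fit.tau_slow_s == pytest.approx(p["tau_slow_s"], rel=1e-4)
        assert fit.triplet_fraction == pytest.approx(p["triplet_fraction"], rel=1e-4)
        assert fit.cpm_khz == pytest.approx(100.0 / p["n_molecules"], rel=1e-4)

    def test_one_component_exact_and_nested_two_component(self, lag_grid):
        params = {"n_molecules": 12.0, "tau_fast_s": 1e-3,
                  "triplet_fraction": 0.0, "structural_parameter": 4.0}
        curve = generate_curve(params, lag_grid, 0.0)
        one = fit_curve(curve, components=1, fix_s=4.0, with_triplet=False)
        assert one.n_molecules == pytest.approx(12.0, rel=1e-6)
        two = fit_curve(curve, components=2, fix_s=4.0, with_triplet=False)
        # nesting: fractions may be degenerate but total N is preserved
        assert two.n_molecules == pytest.approx(12.0, rel=1e-3)

    def test_all_zero_curve_flagged(self):
        lags = np.geomspace(1e-6, 1, 60)
        curve = CorrelationCurve(lags=lags, g=np.zeros(60))
        fit = fit_curve(curve)
        assert "no_correlation" in fit.qc_flags
        assert not np.isfinite(fit.n_molecules)

    def test_relabelling_enforces_tau_order(self, lag_grid):
        params = {"n_molecules": 15.0, "frac_fast": 0.4, "tau_fast_s": 2e-2,
                  "tau_slow_s": 8e-4, "triplet_fraction": 0.0,
                  "structural_parameter": 4.0}
        curve = generate_curve(params, lag_grid, 0.0)
        fit = fit_curve(curve, fix_s=4.0, with_triplet=False)
        assert fit.tau_fast_s < fit.tau_slow_s


class TestTwoStage:
    @pytest.mark.parametrize("seed", range(20))
    def test_recovery_with_free_s_screen(self, seed, lag_grid, two_component_params):
        curve = generate_curve(two_component_params, lag_grid, 0.01, seed=seed,
                               mean_rate_khz=100.0, noise_model="proportional")
        fit = two_stage_fit(curve)
        assert "structural_parameter_out_of_range" not in fit.qc_flags
        assert 0.1 <= fit.free_s_estimate <= 15
        assert fit.n_molecules == pytest.approx(
            two_component_params["n_molecules"], rel=0.05)
        assert fit.frac_fast == pytest.approx(
            two_component_params["frac_fast"], abs=0.05)

    def test_pathological_s_flagged(self, lag_grid):
        # curve generated with an absurdly small structural parameter
        params = {"n_molecules": 10.0, "frac_fast": 0.6, "tau_fast_s": 1e-3,
                  "tau_slow_s": 8e-2, "triplet_fraction": 0.0,
                  "structural_parameter": 0.05, "offset": 0.0}
        curve = generate_curve(params, lag_grid, 0.002, seed=0,
                               noise_model="proportional")
        fit = two_stage_fit(curve, with_triplet=False)
        assert fit.free_s_estimate < 0.1
        assert "structural_parameter_out_of_range" in fit.qc_flags

    def test_stage2_matches_direct_fixed_fit(self, lag_grid, two_component_params):
        curve = generate_curve(two_component_params, lag_grid, 0.0,
                               mean_rate_khz=50.0)
        staged = two_stage_fit(curve)
        direct = fit_curve(curve, fix_s=4.0)
        assert staged.n_molecules == pytest.approx(direct.n_molecules, rel=1e-6)
        assert staged.tau_fast_s == pytest.approx(direct.tau_fast_s, rel=1e-5)


class TestRecoveryInvariant:
    """Median-error tolerances over the study's parameter regimes."""

    @pytest.mark.parametrize("regime", [
        dict(n=12.0, d_fast=9.0, d_slow=0.2, f_slow=0.4),
        dict(n=28.0, d_fast=13.0, d_slow=0.1, f_slow=0.6),
    ])
    def test_median_errors_within_tolerance(self, regime, lag_grid):
        params = {
            "n_molecules": regime["n"],
            "frac_fast": 1 - regime["f_slow"],
            "tau_fast_s": tau_from_d(regime["d_fast"]),
            "tau_slow_s": tau_from_d(regime["d_slow"]),
            "triplet_fraction": 0.15,
            "tau_triplet_s": 20e-6,
            "structural_parameter": 4.0,
            "offset": 0.0,
        }
        rng = np.random.default_rng(42)
        err_n, err_t1, err_t2, err_f = [], [], [], []
        for _ in range(30):
            curve = generate_curve(params, lag_grid, 0.01, seed=rng,
                                   noise_model="proportional")
            fit = fit_curve(curve, fix_s=4.0)
            err_n.append(abs(fit.n_molecules / regime["n"] - 1))
            err_t1.append(abs(fit.tau_fast_s / params["tau_fast_s"] - 1))
            err_t2.append(abs(fit.tau_slow_s / params["tau_slow_s"] - 1))
            err_f.append(abs(fit.frac_slow - regime["f_slow"]))
        assert np.median(err_n) <= 0.05
        assert np.median(err_t1) <= 0.15
        assert np.median(err_t2) <= 0.15
        assert np.median(err_f) <= 0.05
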