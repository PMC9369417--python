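import math

import numpy as np
import pytest

from fcsquant.correlator import autocorrelate_multitau
from fcsquant.model_fit import fit_curve, model_g
from fcsquant.stats import mann_whitney
from fcsquant.synthetic import (GroupSpec, OpticsSpec, SimulationConfig,
                                SpeciesSpec, StudyDesign, TripletSpec,
                                effective_volume_um3, generate_curve,
                                generate_intensity_table, generate_population,
                                make_lag_grid, simulate_trace)

from conftest import tau_from_d


def _one_molecule_cv(optics: OpticsSpec, box_xy: float, box_z: float) -> float:
    """mean_molecules_in_cv that rounds to exactly one simulated molecule."""
    return effective_volume_um3(optics) / (box_xy**2 * box_z)


class TestSpecs:
    def test_species_validation(self):
        with pytest.raises(ValueError):
            SpeciesSpec(diffusion_um2_s=-1.0)
        with pytest.raises(ValueError):
            SpeciesSpec(diffusion_um2_s=1.0, fraction=1.5)
        with pytest.raises(ValueError):
            SpeciesSpec(diffusion_um2_s=1.0, brightness_khz=-2.0)

    def test_optics_validation(self):
        with pytest.raises(ValueError):
            OpticsSpec(w0_um=0.0)
        with pytest.raises(ValueError):
            OpticsSpec(structural_parameter=0.5)

    def test_triplet_validation(self):
        with pytest.raises(ValueError):
            TripletSpec(dark_fraction=1.0)
        with pytest.raises(ValueError):
            TripletSpec(relaxation_time_s=0.0)

    def test_config_fraction_sum(self):
        with pytest.raises(ValueError):
            SimulationConfig(species=[SpeciesSpec(10.0, 0.5), SpeciesSpec(1.0, 0.4)])

    def test_config_box_too_small(self):
        with pytest.raises(ValueError):
            SimulationConfig(box_xy_um=0.5)

    def test_config_timestep_exceeds_bin(self):
        with pytest.raises(ValueError):
            SimulationConfig(bin_width_s=2e-6, timestep_s=4e-6)


class TestSimulateTrace:
    def test_zero_brightness_zero_background_all_zero(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(10.0, 1.0, brightness_khz=0.0)], triplet=None,
            mean_molecules_in_cv=5.0, bin_width_s=1e-5, duration_s=0.01,
            repetitions=2)
        traces = simulate_trace(cfg, seed=0)
        assert len(traces) == 2
        for tr in traces:
            assert np.all(tr.counts == 0)

    def test_pinned_molecule_mean_rate_approaches_brightness(self):
        # one immobile molecule at the focus: MDF = 1, so the count rate
        # converges to the per-molecule brightness
        optics = OpticsSpec()
        cfg = SimulationConfig(
            species=[SpeciesSpec(0.0, 1.0, brightness_khz=50.0)], triplet=None,
            mean_molecules_in_cv=_one_molecule_cv(optics, 6 * 0.22, 6 * 4 * 0.22),
            bin_width_s=1e-5, duration_s=0.1, repetitions=1,
            initial_positions=np.zeros((1, 3)))
        tr = simulate_trace(cfg, seed=1)[0]
        assert tr.meta["ground_truth"]["n_simulated_molecules"] == 1
        assert tr.mean_rate_khz == pytest.approx(50.0, rel=0.05)

    def test_occupancy_oracle(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(10.0, 1.0, 20.0)], triplet=None,
            mean_molecules_in_cv=10.0, bin_width_s=1e-5, duration_s=0.25,
            repetitions=1)
        tr = simulate_trace(cfg, seed=2, record_occupancy=True)[0]
        occ = tr.meta["occupancy_mean"]
        se = tr.meta["occupancy_se"]
        assert abs(occ - 10.0) <= max(3 * se, 0.5)

    def test_mean_rate_matches_mdf_volume_ratio(self):
        # mean rate = brightness * occupancy * 2^-3/2 (MDF volume ratio),
        # checked against the direct occupancy measurement
        cfg = SimulationConfig(
            species=[SpeciesSpec(5.0, 1.0, 40.0)], triplet=None,
            mean_molecules_in_cv=8.0, bin_width_s=1e-5, duration_s=0.25,
            repetitions=1)
        tr = simulate_trace(cfg, seed=3, record_occupancy=True)[0]
        expected = 40.0 * tr.meta["occupancy_mean"] * 2**-1.5
        assert tr.mean_rate_khz == pytest.approx(expected, rel=0.1)

    def test_triplet_dims_mean_rate(self):
        # one immobile molecule at the focus: blinking with equilibrium dark
        # fraction T scales the count rate by exactly (1 - T)
        optics = OpticsSpec()
        base = dict(species=[SpeciesSpec(0.0, 1.0, 50.0)],
                    mean_molecules_in_cv=_one_molecule_cv(
                        optics, 6 * 0.22, 6 * 4 * 0.22),
                    bin_width_s=2e-6, duration_s=0.1, repetitions=1,
                    initial_positions=np.zeros((1, 3)))
        bright = simulate_trace(SimulationConfig(triplet=None, **base), seed=4)[0]
        dark = simulate_trace(SimulationConfig(
            triplet=TripletSpec(0.3, 20e-6), **base), seed=4)[0]
        ratio = dark.mean_rate_khz / bright.mean_rate_khz
        assert ratio == pytest.approx(0.7, abs=0.04)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(10.0, 1.0, 20.0)], triplet=None,
            mean_molecules_in_cv=3.0, bin_width_s=1e-5, duration_s=0.02,
            repetitions=1)
        a = simulate_trace(cfg, seed=7)[0]
        b = simulate_trace(cfg, seed=7)[0]
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_single_species_recovery(self):
        # correlate + fit round trip on Brownian-dynamics traces: median
        # relative error of N and D below 15% across seeds
        err_n, err_d = [], []
        for seed in range(20):
            cfg = SimulationConfig(
                species=[SpeciesSpec(10.0, 1.0, 50.0)], triplet=None,
                mean_molecules_in_cv=5.0, bin_width_s=1e-5, duration_s=1.0,
                repetitions=1)
            tr = simulate_trace(cfg, seed=seed)[0]
            fit = fit_curve(autocorrelate_multitau(tr), components=1,
                            fix_s=4.0, with_triplet=False)
            err_n.append(abs(fit.n_molecules / 5.0 - 1))
            err_d.append(abs(tau_from_d(10.0) / fit.tau_fast_s - 1))
        assert np.median(err_n) <= 0.15
        assert np.median(err_d) <= 0.15


class TestGenerateCurve:
    def test_zero_noise_identity(self, lag_grid, two_component_params):
        curve = generate_curve(two_component_params, lag_grid, 0.0)
        np.testing.assert_allclose(
            curve.g, model_g(lag_grid, **two_component_params), rtol=1e-14)

    def test_amplitude_is_one_over_n(self, lag_grid):
        params = {"n_molecules": 10.0, "tau_fast_s": 1e-3,
                  "triplet_fraction": 0.0}
        curve = generate_curve(params, lag_grid, 0.0)
        assert curve.g[0] == pytest.approx(0.1, rel=2e-3)

    def test_strictly_decreasing_for_valid_params(self, lag_grid):
        rng = np.random.default_rng(5)
        for _ in range(5):
            params = {
                "n_molecules": rng.uniform(5, 50),
                "frac_fast": rng.uniform(0.2, 0.8),
                "tau_fast_s": 10 ** rng.uniform(-4, -3),
                "tau_slow_s": 10 ** rng.uniform(-2.5, -1),
                "triplet_fraction": rng.uniform(0, 0.4),
                "tau_triplet_s": 20e-6,
            }
            curve = generate_curve(params, lag_grid, 0.0)
            assert np.all(np.diff(curve.g) < 0)

    def test_negative_noise_scale_errors(self, lag_grid):
        with pytest.raises(ValueError):
            generate_curve({"n_molecules": 10, "tau_fast_s": 1e-3},
                           lag_grid, -0.01)

    def test_seed_reproducibility(self, lag_grid, two_component_params):
        a = generate_curve(two_component_params, lag_grid, 0.01, seed=9)
        b = generate_curve(two_component_params, lag_grid, 0.01, seed=9)
        np.testing.assert_array_equal(a.g, b.g)

    def test_ground_truth_retained(self, lag_grid, two_component_params):
        curve = generate_curve(two_component_params, lag_grid, 0.01, seed=0)
        assert curve.meta["ground_truth"]["n_molecules"] == pytest.approx(20.85)


def _tiny_design(**group_overrides) -> StudyDesign:
    defaults = dict(strain="A", condition="glucose", n_cells=5,
                    n_molecules_median=20.0, repetitions=2)
    defaults.update(group_overrides)
    return StudyDesign(groups=[GroupSpec(**defaults)], n_lags=40)


class TestGeneratePopulation:
    def test_zero_dispersion_degenerates_to_medians(self):
        design = _tiny_design(n_molecules_cv=0.0, cpm_cv=0.0,
                              frac_slow_scale=0.0, d_cv=0.0)
        records = generate_population(design, seed=0)
        for rec in records:
            assert rec.truth["n_molecules"] == pytest.approx(20.0)
            assert rec.truth["frac_slow"] == pytest.approx(0.4)

    def test_seed_determinism(self):
        design = _tiny_design()
        a = generate_population(design, seed=3)
        b = generate_population(design, seed=3)
        for ra, rb in zip(a, b):
            assert ra.truth == rb.truth
            for ca, cb in zip(ra.curves, rb.curves):
                np.testing.assert_array_equal(ca.g, cb.g)

    def test_lognormal_median_property(self):
        design = _tiny_design(n_cells=200, n_molecules_median=25.0,
                              n_molecules_cv=0.2, repetitions=1)
        records = generate_population(design, seed=11)
        sample_median = np.median([r.truth["n_molecules"] for r in records])
        assert sample_median == pytest.approx(25.0, rel=0.05)

    def test_curve_count_and_mean_rate(self):
        design = _tiny_design(repetitions=3, cpm_khz_median=8.0,
                              n_molecules_cv=0.0, cpm_cv=0.0)
        records = generate_population(design, seed=0)
        for rec in records:
            assert len(rec.curves) == 3
            assert rec.curves[0].mean_rate_khz == pytest.approx(8.0 * 20.0)


class TestIntensityTable:
    def test_zero_dispersion(self):
        design = _tiny_design(intensity_median=1000.0, intensity_cv=0.0)
        table = generate_intensity_table(design, seed=0)
        np.testing.assert_allclose(table["integrated_intensity"], 1000.0)

    def test_determinism(self):
        design = _tiny_design()
        a = generate_intensity_table(design, seed=5)
        b = generate_intensity_table(design, seed=5)
        assert a.equals(b)

    def test_power_between_separated_groups(self):
        groups = [
            GroupSpec(strain="lo", condition="c", n_cells=100,
                      n_molecules_median=20.0, intensity_median=1000.0,
                      intensity_cv=0.05),
            GroupSpec(strain="hi", condition="c", n_cells=100,
                      n_molecules_median=20.0, intensity_median=1500.0,
                      intensity_cv=0.05),
        ]
        table = generate_intensity_table(StudyDesign(groups=groups), seed=1)
        a = table.loc[table["strain"] == "lo", "integrated_intensity"]
        b = table.loc[table["strain"] == "hi", "integrated_intensity"]
        assert mann_whitney(a, b).p_value < 0.05
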