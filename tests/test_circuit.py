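"""Equivalent-circuit model: building blocks, calibration, perturbations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvscan import circuit
from guvscan.circuit import (
    BASELINE_PHASES,
    MODE_FREQUENCIES,
    RingResonatorModel,
    calibrate,
    delta_s21,
    dissipated_fraction,
    find_dip,
    line_abcd,
    network_response,
    s21_spectrum,
)
from guvscan.errors import CalibrationError, InputError, ModelInstabilityError, OutOfLinearRangeError


class TestBuildingBlocks:
    def test_quarter_wave_line_closed_form(self):
        z0 = 63.0
        beta = 2 * np.pi / 4.0  # wavelength 4 m -> quarter-wave at length 1 m
        a, b, c, d = line_abcd(z0, 1j * beta, 1.0)
        assert abs(a) < 1e-12 and abs(d) < 1e-12
        assert b == pytest.approx(1j * z0, abs=1e-10)
        assert c == pytest.approx(1j / z0, abs=1e-12)

    @given(
        beta_l=st.floats(0.1, 6.0),
        alpha_l=st.floats(0.0, 0.5),
        z0=st.floats(20.0, 120.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_line_reciprocity_determinant(self, beta_l, alpha_l, z0):
        # AD - BC = 1 for every transmission-line two-port (reciprocity)
        a, b, c, d = line_abcd(z0, alpha_l + 1j * beta_l, 1.0)
        assert a * d - b * c == pytest.approx(1.0, abs=1e-10)

    def test_decoupled_through(self, model):
        bare = model.replace(coupling_capacitance=0.0, feed_delay=0.0, feed_phase_deg=0.0)
        grid = np.linspace(1e9, 10e9, 101)
        s11, s21 = network_response(bare, grid)
        assert np.allclose(np.abs(s21), 1.0, atol=1e-12)
        assert np.allclose(np.abs(s11), 0.0, atol=1e-12)


class TestSpectrum:
    def test_dips_at_calibrated_modes(self, model):
        grid = np.linspace(1e9, 10e9, 1801)
        spec = s21_spectrum(model, grid)
        mag = np.abs(spec.s21)
        for f_mode in model.mode_frequencies:
            i = int(np.argmin(np.abs(grid - f_mode)))
            window = mag[max(i - 40, 0) : i + 41]
            assert mag[i] == pytest.approx(window.min(), abs=1e-6)

    def test_passivity_everywhere(self, model):
        grid = np.linspace(0.5e9, 12e9, 4001)
        s11, s21 = network_response(model, grid)
        assert np.all(np.abs(s11) ** 2 + np.abs(s21) ** 2 <= 1 + 1e-9)

    def test_lossless_uncoupled_is_unit_transmission(self, model):
        bare = model.replace(coupling_capacitance=0.0, loss_per_length=0.0)
        spec = s21_spectrum(bare, np.linspace(1e9, 10e9, 50))
        assert np.allclose(np.abs(spec.s21), 1.0, atol=1e-12)

    def test_empty_grid_rejected(self, model):
        with pytest.raises(InputError):
            s21_spectrum(model, [])

    def test_dissipated_power_fraction_at_first_mode(self, model):
        frac = dissipated_fraction(model, model.mode_frequencies[0])
        assert 0.3 <= frac <= 0.6

    def test_dip_location_matches_grid_search(self, model):
        # analytic (refined) dip vs brute-force minimum on a 10 kHz grid
        for f_mode in model.mode_frequencies:
            grid = np.arange(f_mode - 3e7, f_mode + 3e7, 1e4)
            _, s21 = network_response(model, grid)
            brute = grid[int(np.argmin(np.abs(s21)))]
            assert abs(find_dip(model, f_mode) - brute) <= 1e4

    def test_dip_depth_monotone_in_coupling(self, model):
        scales = np.linspace(0.8, 1.2, 7)
        depths = []
        for sc in scales:
            m = model.replace(coupling_capacitance=model.coupling_capacitance * sc)
            d = find_dip(m, model.mode_frequencies[0])
            depths.append(1.0 - abs(network_response(m, d)[1]))
        assert np.all(np.diff(depths) > 0)


class TestCalibration:
    def test_modes_and_phases_match_published_targets(self, model):
        for f_target, f_got in zip(MODE_FREQUENCIES, model.mode_frequencies):
            assert abs(f_got / f_target - 1) < 1e-3
        for f_target, theta in zip(MODE_FREQUENCIES, BASELINE_PHASES):
            phase = np.rad2deg(np.angle(network_response(model, f_target)[1]))
            err = (phase - theta + 180.0) % 360.0 - 180.0
            assert abs(err) < 0.5

    def test_recalibration_to_own_dips_is_a_fixed_point(self, model):
        again = calibrate(model, model.mode_frequencies)
        for name in ("ring_circumference", "eps_eff_slope", "loss_per_length", "coupling_capacitance"):
            a, b = getattr(model, name), getattr(again, name)
            assert abs(b - a) <= 1e-6 * abs(a)

    def test_optimizer_beats_coarse_dispersion_grid(self, model):
        # residual of the calibrated model vs an exhaustive coarse grid over
        # the two dispersion-law coefficients
        def residual(m):
            return max(
                abs(find_dip(m, f) / f - 1) for f in MODE_FREQUENCIES
            )

        calibrated = residual(model)
        grid_best = np.inf
        for base in np.linspace(0.9, 1.1, 5) * model.eps_eff_base + 0.013:
            for slope in np.linspace(0.9, 1.1, 5) * model.eps_eff_slope + 0.007:
                m = model.replace(eps_eff_base=float(base), eps_eff_slope=float(slope))
                grid_best = min(grid_best, residual(m))
        assert calibrated <= grid_best

    def test_unreachable_targets_raise(self, model):
        with pytest.raises((CalibrationError, InputError)):
            calibrate(model, (2.7e9, 2.8e9, 3.0e9))

    def test_invalid_parameter_named_in_error(self, model):
        bad = dataclasses.replace(model, ring_circumference=-1.0)
        with pytest.raises(ModelInstabilityError) as err:
            network_response(bad, 2.7e9)
        assert "ring_circumference" in str(err.value)


class TestDeltaS21:
    def test_null_perturbation_is_exactly_zero(self, model):
        assert delta_s21(model, 0.0, 2.7e9) == 0.0

    def test_matches_finite_difference_recompute(self, model):
        dc = 1e-4 * model.split_gap_capacitance
        direct = delta_s21(model, dc, 2.7e9)
        pert = model.replace(split_gap_capacitance=model.split_gap_capacitance + dc)
        recompute = network_response(pert, 2.7e9)[1] - network_response(model, 2.7e9)[1]
        assert abs(direct - recompute) < 1e-12

    def test_local_linearity(self, model):
        dc = 1e-4 * model.split_gap_capacitance
        ratio = abs(delta_s21(model, 2 * dc, 2.7e9)) / abs(delta_s21(model, dc, 2.7e9))
        assert 1.98 <= ratio <= 2.02

    def test_out_of_linear_range_rejected(self, model):
        with pytest.raises(OutOfLinearRangeError):
            delta_s21(model, 2.0 * model.split_gap_capacitance, 2.7e9)
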