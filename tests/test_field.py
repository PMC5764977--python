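"""Electrostatic gap-field solver: exact identities, analytic oracles,
convergence and the physics of the layered stack."""

import dataclasses

import numpy as np
import pytest

from guvscan import field as F
from guvscan.errors import InputError, RangeError


@pytest.fixture(scope="module")
def coplanar_geometry():
    """Zero-thickness metal in vacuum: the conformal-map reference case."""
    return F.SensorGeometry(
        metal_thickness=0.0,
        substrate_permittivity=1.0,
        pdms_permittivity=1.0,
        channel_height=1.0,  # lid far outside the solved domain
    )


class TestDiscreteIdentities:
    def test_flux_residual_is_negligible(self, water_map):
        assert water_map.residual < 1e-8

    def test_potential_antisymmetric_in_x(self, water_map):
        phi = np.real(water_map.phi)
        assert np.max(np.abs(phi + phi[:, ::-1])) < 1e-10

    def test_kernel_euler_identity(self, geometry, water_map):
        # sum of layer weights x permittivities equals the capacitance exactly
        weights, fmap = F.sensitivity_kernel(geometry, water_map.stack, fmap=water_map)
        _, total = F.capacitance(fmap)
        recon = sum(w * fmap.eps[fmap.labels == name][0] for name, w in weights.items())
        assert abs(recon - total) <= 1e-12 * abs(total)

    def test_capacitance_linear_in_global_permittivity_scale(self, geometry):
        # every permittivity in the domain (including substrate and lid)
        # doubles, so the capacitance doubles exactly
        doubled = dataclasses.replace(
            geometry,
            substrate_permittivity=2 * geometry.substrate_permittivity,
            pdms_permittivity=2 * geometry.pdms_permittivity,
        )
        c1 = F.gap_capacitance(geometry, F.uniform_stack(40.0), 16)[0]
        c2 = F.gap_capacitance(doubled, F.uniform_stack(80.0), 16)[0]
        assert abs(c2 / c1 - 2.0) < 1e-9

    def test_parallel_and_perpendicular_fractions_sum_to_one(self, water_map):
        mask = water_map.region_mask("measurement")
        w = np.real(water_map.eps)[mask] * water_map.cell_areas[mask]
        par = np.sum(w * np.abs(water_map.ex[mask]) ** 2)
        perp = np.sum(w * np.abs(water_map.ey[mask]) ** 2)
        frac = F.parallel_energy_fraction(water_map, "measurement")
        assert frac + perp / (par + perp) == pytest.approx(1.0, abs=1e-12)


class TestAnalyticOracles:
    def test_capacitance_matches_elliptic_integral_closed_form(self, coplanar_geometry):
        s = coplanar_geometry.slot_width
        fmap = F.solve_potential(
            coplanar_geometry,
            F.uniform_stack(1.0),
            resolution=24,
            x_extent=30 * s,
            y_top=30 * s,
            y_bottom=30 * s,
            electrode_halfwidth=0.5 * s + 3 * s,
        )
        per_m, _ = F.capacitance(fmap)
        ref = F.coplanar_strip_capacitance(s, 3 * s)
        assert abs(per_m.real / ref - 1) < 0.02

    def test_centerline_intensity_matches_conformal_profile(self, coplanar_geometry):
        s = coplanar_geometry.slot_width
        fmap = F.solve_potential(
            coplanar_geometry,
            F.uniform_stack(1.0),
            resolution=96,
            x_extent=30 * s,
            y_top=30 * s,
            y_bottom=30 * s,
        )
        ys, prof = F.field_profile(fmap, y_max=2 * s)
        ratio = prof / prof[0]
        ref = F.coplanar_centerline_intensity(ys, s) / F.coplanar_centerline_intensity(ys[0], s)
        assert np.max(np.abs(ratio - ref) / ref) < 0.02
        # the half-way point of the analytic profile: y = s/2 -> 1/2
        i = int(np.argmin(np.abs(ys - s / 2)))
        assert ratio[i] == pytest.approx(0.5, rel=0.02)

    def test_grid_convergence_on_default_geometry(self, geometry, water_map):
        c24 = F.capacitance(water_map)[0].real
        c48 = F.gap_capacitance(geometry, F.uniform_stack(78.4), 48)[0].real
        assert abs(c48 / c24 - 1) < 0.01


class TestLayeredPhysics:
    def test_profile_positive_and_monotone_above_surface(self, water_map):
        ys, prof = F.field_profile(water_map)
        assert np.all(prof > 0)
        assert np.all(np.diff(prof) < 0)

    def test_gap_field_dominates_channel_top(self, geometry, water_map):
        ys, prof = F.field_profile(water_map)
        i_top = int(np.argmin(np.abs(ys - geometry.channel_height)))
        assert prof[0] / prof[i_top] >= 10.0

    def test_parallel_fraction_exceeds_90_percent_in_measurement_region(self, geometry):
        fmap = F.solve_potential(geometry, F.membrane_stack(2.7e9), resolution=24)
        assert F.parallel_energy_fraction(fmap, "measurement") > 0.9

    def test_slot_interior_is_parallel_plate_like(self, water_map):
        assert F.parallel_energy_fraction(water_map, "slot") >= 0.99

    def test_elevation_factor_definition_and_monotonicity(self, water_map):
        assert F.elevation_factor(water_map, 0.0) == 1.0
        f50 = F.elevation_factor(water_map, 50e-9, thickness=5e-9)
        f100 = F.elevation_factor(water_map, 100e-9, thickness=5e-9)
        f200 = F.elevation_factor(water_map, 200e-9, thickness=5e-9)
        assert 0 < f200 < f100 < f50 < 1

    def test_elevation_factor_out_of_domain(self, water_map):
        with pytest.raises(RangeError):
            F.elevation_factor(water_map, 1.0)

    def test_kernel_prediction_matches_full_resolve(self, geometry):
        stack = F.membrane_stack(2.7e9)
        weights, fmap = F.sensitivity_kernel(geometry, stack, 24)
        perturbed = F.LayerStack(
            layers=tuple(
                dataclasses.replace(l, permittivity=l.permittivity + 1.0) if l.analyte else l
                for l in stack.layers
            )
        )
        actual = F.gap_capacitance(geometry, perturbed, 24)[1] - F.capacitance(fmap)[1]
        assert abs(weights["membrane"] - actual) / abs(actual) < 0.03

    def test_kernel_weight_ratio_tracks_elevation_factor(self, geometry, water_map):
        w0, _ = F.sensitivity_kernel(geometry, F.membrane_stack(2.7e9), 24)
        w100, _ = F.sensitivity_kernel(geometry, F.membrane_stack(2.7e9, elevation=100e-9), 24)
        ratio = abs(w100["membrane"]) / abs(w0["membrane"])
        factor = F.elevation_factor(water_map, 100e-9, thickness=5e-9)
        assert ratio == pytest.approx(factor, rel=0.05)

    def test_high_permittivity_layer_increases_capacitance(self, geometry):
        base = F.gap_capacitance(geometry, F.uniform_stack(78.4), 16)[0].real
        stack = F.LayerStack(
            layers=(
                F.Layer("film", 50e-9, 200.0, analyte=True),
                F.Layer("medium", np.inf, 78.4),
            )
        )
        assert F.gap_capacitance(geometry, stack, 16)[0].real > base


class TestValidation:
    def test_resolution_floor(self, geometry):
        with pytest.raises(InputError):
            F.solve_potential(geometry, F.uniform_stack(1.0), resolution=8)

    def test_stack_needs_exactly_one_analyte(self):
        with pytest.raises(InputError):
            F.LayerStack(
                layers=(
                    F.Layer("a", 1e-9, 2.0, analyte=True),
                    F.Layer("b", np.inf, 2.0, analyte=True),
                )
            ).validate()

    def test_geometry_rejects_nonpositive_lengths(self):
        with pytest.raises(InputError):
            F.SensorGeometry(slot_width=-1.0).validate()
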