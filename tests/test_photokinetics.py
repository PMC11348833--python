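"""Two-state photoswitch kinetics: rates, PSS, closed-form integration."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from ppsim.photokinetics import (
    ConcentrationField,
    PhotoswitchSpec,
    RateConstants,
    addressability_report,
    field_kinetics,
    integrate_two_state,
    pss_fraction,
    rate_constant,
    thermal_rate,
)
from ppsim.transport import FluenceMap


def expm_oracle(c_e0, c_z0, rates, t):
    """Matrix-exponential solution of the 2x2 linear system (oracle)."""
    kez, kze = rates.k_ez_total, rates.k_ze_total
    A = np.array([[-kez, kze], [kez, -kze]])
    return expm(A * t) @ np.array([c_e0, c_z0])


class TestRateConstant:
    def test_hand_computed_value(self):
        k = rate_constant(1e4, 0.5, 1e-9)
        assert k == pytest.approx(1.1513e-2, rel=1e-4)

    def test_dark_limit(self):
        assert rate_constant(1e4, 0.5, 0.0) == 0.0

    @given(
        eps=st.floats(0, 1e5),
        phi=st.floats(0, 1),
        epf=st.floats(0, 1e-3),
        factor=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_linearity_in_each_argument(self, eps, phi, epf, factor):
        base = rate_constant(eps, phi, epf)
        assert rate_constant(eps * factor, phi, epf) == pytest.approx(base * factor, rel=1e-12)
        assert rate_constant(eps, phi, epf * factor) == pytest.approx(base * factor, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rate_constant(-1.0, 0.5, 1e-9)


class TestThermalRate:
    def test_values(self):
        assert thermal_rate(np.log(2.0)) == pytest.approx(1.0, rel=1e-12)
        assert thermal_rate(np.inf) == 0.0
        assert thermal_rate(3600.0) == pytest.approx(1.9254e-4, rel=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            thermal_rate(0.0)


class TestPssFraction:
    def test_ideal_addressability_complete_conversion(self):
        rates = RateConstants(k_ez_hv=0.1, k_ze_hv=0.0, k_thermal=0.0)
        assert pss_fraction(rates) == 1.0

    def test_symmetric_rates_half(self):
        assert pss_fraction(RateConstants(0.02, 0.02, 0.0)) == 0.5

    def test_thermal_back_reaction_shifts_pss(self):
        rates = RateConstants(0.02, 0.01, 0.01, thermal_direction="Z->E")
        assert pss_fraction(rates) == pytest.approx(0.5, rel=1e-12)

    def test_thermal_direction_sign(self):
        fwd = RateConstants(0.02, 0.01, 0.01, thermal_direction="E->Z")
        assert pss_fraction(fwd) == pytest.approx(0.03 / 0.04, rel=1e-12)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            pss_fraction(RateConstants(0.0, 0.0, 0.0))

    @given(
        kez=st.floats(1e-6, 10.0),
        kze=st.floats(1e-6, 10.0),
        kd=st.floats(0.0, 10.0),
        bump=st.floats(1e-6, 5.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_rates(self, kez, kze, kd, bump):
        base = pss_fraction(RateConstants(kez, kze, kd, "Z->E"))
        assert pss_fraction(RateConstants(kez + bump, kze, kd, "Z->E")) >= base
        assert pss_fraction(RateConstants(kez, kze + bump, kd, "Z->E")) <= base
        assert pss_fraction(RateConstants(kez, kze, kd + bump, "Z->E")) <= base


class TestIntegrateTwoState:
    def test_t_zero_identity(self):
        c_e, c_z = integrate_two_state(3e-6, 7e-6, RateConstants(0.1, 0.2, 0.01), 0.0)
        assert (c_e, c_z) == (3e-6, 7e-6)

    def test_long_time_reaches_pss(self):
        rates = RateConstants(0.3, 0.1, 0.05, "Z->E")
        kappa = rates.kappa
        c_e, c_z = integrate_two_state(1e-5, 0.0, rates, 50.0 / kappa)
        assert c_z / (c_e + c_z) == pytest.approx(pss_fraction(rates), abs=1e-12)

    def test_matches_matrix_exponential_oracle(self):
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(100):
            kez, kze, kd = rng.uniform(0, 1, 3)
            direction = "Z->E" if rng.random() < 0.5 else "E->Z"
            rates = RateConstants(kez, kze, kd, direction)
            c_e0, c_z0 = rng.uniform(0, 1e-4, 2)
            t = rng.uniform(0, 100)
            c_e, c_z = integrate_two_state(c_e0, c_z0, rates, t)
            ref = expm_oracle(c_e0, c_z0, rates, t)
            scale = c_e0 + c_z0
            worst = max(worst, abs(c_e - ref[0]) / scale, abs(c_z - ref[1]) / scale)
            assert abs((c_e + c_z) - scale) < 1e-12 * scale
        assert worst < 1e-10

    def test_dark_half_life_semantics(self):
        """After one thermal half-life in the dark, exactly half of the
        non-stable isomer has converted."""
        t_half = 137.0
        rates = RateConstants(0.0, 0.0, thermal_rate(t_half), "Z->E")
        c_e, c_z = integrate_two_state(0.0, 1e-5, rates, t_half)
        assert c_z == pytest.approx(0.5e-5, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            integrate_two_state(1e-6, 1e-6, RateConstants(0.1, 0.1), -1.0)


def _uniform_fluence(shape, value, wavelengths=(460.0,)):
    return FluenceMap(
        fluence={wl: np.full(shape, value) for wl in wavelengths},
        absorbed_w={},
        ledger={},
        voxel_size_um=(40.0, 40.0, 40.0),
    )


class TestFieldKinetics:
    @pytest.fixture
    def spec(self):
        return PhotoswitchSpec.synthetic_azobenzene_inhibitor()

    def test_uniform_flux_matches_scalar_solution(self, spec):
        shape = (4, 5, 6)
        fmap = _uniform_fluence(shape, 0.5)
        field = ConcentrationField.uniform(shape, 1e-5, f_z=1.0)
        out = field_kinetics(field, fmap, spec, t=10.0)
        eps_e, eps_z, phi_ez, phi_ze = spec.at(460.0)
        from ppsim.transport import irradiance_to_photon_flux

        epf = irradiance_to_photon_flux(0.5, 460.0)
        rates = RateConstants(
            rate_constant(eps_e, phi_ez, epf),
            rate_constant(eps_z, phi_ze, epf),
            thermal_rate(spec.t_half_s),
            spec.thermal_direction,
        )
        ce_ref, cz_ref = integrate_two_state(0.0, 1e-5, rates, 10.0)
        np.testing.assert_allclose(out.c_z, cz_ref, rtol=1e-12)
        np.testing.assert_allclose(out.c_e, ce_ref, rtol=1e-12)

    def test_two_wavelength_rates_add(self, spec):
        """Per-voxel kappa for a 460+620 nm map equals the sum of the
        single-wavelength photochemical rates plus the thermal rate."""
        from ppsim.photokinetics import field_rates

        shape = (3, 3, 3)
        both = field_rates(_uniform_fluence(shape, 0.2, (460.0, 620.0)), spec)
        blue = field_rates(_uniform_fluence(shape, 0.2, (460.0,)), spec)
        red = field_rates(_uniform_fluence(shape, 0.2, (620.0,)), spec)
        np.testing.assert_allclose(
            both.kappa, blue.k_ez_hv + blue.k_ze_hv + red.k_ez_hv + red.k_ze_hv + both.k_thermal,
            rtol=1e-12,
        )

    def test_dark_region_evolves_thermally_only(self, spec):
        shape = (4, 1, 1)
        fl = np.zeros(shape)
        fl[:2] = 1.0  # half-illuminated slab
        fmap = FluenceMap(fluence={460.0: fl}, absorbed_w={}, ledger={}, voxel_size_um=(40,) * 3)
        field = ConcentrationField.uniform(shape, 1e-5, f_z=0.0)  # start all-E
        out = field_kinetics(field, fmap, spec, t=30.0)
        kd = thermal_rate(spec.t_half_s)
        rates = RateConstants(0.0, 0.0, kd, spec.thermal_direction)
        _, cz_dark = integrate_two_state(1e-5, 0.0, rates, 30.0)
        np.testing.assert_allclose(out.c_z[2:], cz_dark, rtol=1e-12)
        assert (out.c_z[:2] != out.c_z[2:]).all()

    def test_mass_conserved_voxelwise(self, spec):
        shape = (5, 5, 5)
        fmap = _uniform_fluence(shape, 2.0)
        field = ConcentrationField.uniform(shape, 1e-5, f_z=0.7)
        out = field_kinetics(field, fmap, spec, t=123.0)
        np.testing.assert_allclose(out.c_tot, 1e-5, rtol=1e-12)

    def test_grid_mismatch_rejected(self, spec):
        field = ConcentrationField.uniform((3, 3, 3), 1e-5)
        with pytest.raises(ValueError, match="grids differ"):
            field_kinetics(field, _uniform_fluence((4, 4, 4), 1.0), spec, pss=True)

    def test_dark_limit_relaxes_to_stable_isomer(self, spec):
        """With zero flux everywhere the field relaxes to 100% of the
        thermally stable isomer (Z for this compound)."""
        shape = (3, 3, 3)
        fmap = _uniform_fluence(shape, 0.0)
        field = ConcentrationField.uniform(shape, 1e-5, f_z=0.0)
        out = field_kinetics(field, fmap, spec, t=1e6 * spec.t_half_s / 100)
        np.testing.assert_allclose(out.f_z, 1.0, atol=1e-9)


class TestSpecAndReport:
    def test_spectra_round_trip(self, tmp_path):
        spec = PhotoswitchSpec.synthetic_azobenzene_inhibitor()
        spec.to_files(tmp_path / "drug.csv", tmp_path / "drug.json")
        back = PhotoswitchSpec.from_files(tmp_path / "drug.json")
        np.testing.assert_allclose(back.eps_e, spec.eps_e)
        assert back.t_half_s == spec.t_half_s
        assert back.thermal_direction == spec.thermal_direction

    def test_extrapolation_warns(self):
        spec = PhotoswitchSpec.synthetic_azobenzene_inhibitor()
        with pytest.warns(UserWarning, match="outside"):
            spec.at(900.0)

    def test_one_sided_condition_detected(self):
        wl = np.array([400.0, 500.0])
        spec = PhotoswitchSpec(
            name="ideal",
            wavelengths_nm=wl,
            eps_e=np.array([1e4, 0.0]),
            eps_z=np.array([0.0, 1e4]),
            phi_ez=np.array([0.5, 0.5]),
            phi_ze=np.array([0.5, 0.5]),
            t_half_s=np.inf,
        )
        rep = addressability_report(spec, (400.0, 500.0))
        row = rep[rep.wavelength_nm == 400.0].iloc[0]
        assert row.condition_one_sided
        # complete conversion at the one-sided wavelength
        assert row.pss_f_z == 1.0

    def test_dominance_threshold(self):
        wl = np.array([400.0, 500.0])
        spec = PhotoswitchSpec(
            name="leaky",
            wavelengths_nm=wl,
            eps_e=np.array([1e4, 1e4]),
            eps_z=np.array([1e3, 1e3]),  # ratio 10 with equal yields
            phi_ez=np.array([0.5, 0.5]),
            phi_ze=np.array([0.5, 0.5]),
            t_half_s=np.inf,
        )
        rep = addressability_report(spec, (400.0,), ratio_threshold=100.0)
        assert not rep.iloc[0].condition_dominant
        rep = addressability_report(spec, (400.0,), ratio_threshold=10.0)
        assert rep.iloc[0].condition_dominant
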