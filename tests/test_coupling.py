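"""Light-chemistry coupling: drug absorption feedback and fixed points."""

import numpy as np
import pytest

import ppsim
from ppsim.constants import LN10
from ppsim.coupling import coupled_solve, drug_absorption, time_marched_solve
from ppsim.phantom import build_layered_slab
from ppsim.photokinetics import (
    ConcentrationField,
    PhotoswitchSpec,
    RateConstants,
    integrate_two_state,
    rate_constant,
    thermal_rate,
)
from ppsim.sources import SourceSpec
from ppsim.transport import RunConfig, irradiance_to_photon_flux, run_mc

WL = 460.0


@pytest.fixture(scope="module")
def spec():
    return PhotoswitchSpec.synthetic_azobenzene_inhibitor()


@pytest.fixture
def absorber_slab(medium_factory):
    cls = medium_factory(0.1, 0.0, wavelengths=(WL,))
    return build_layered_slab([(cls, 10_000.0)], (20, 20, 40), (500.0, 500.0, 250.0))


def pencil(power):
    return SourceSpec(
        kind="pencil", position_um=(5000.0, 5000.0, 0.5), power_w={WL: power}
    )


class TestDrugAbsorption:
    def test_zero_concentration(self, spec):
        field = ConcentrationField.uniform((3, 3, 3), 0.0)
        assert drug_absorption(field, spec, WL).max() == 0.0

    def test_hand_computed_value(self):
        wl = np.array([400.0, 500.0])
        spec = PhotoswitchSpec(
            name="x", wavelengths_nm=wl,
            eps_e=np.zeros(2), eps_z=np.full(2, 1e4),
            phi_ez=np.full(2, 0.5), phi_ze=np.full(2, 0.5), t_half_s=np.inf,
        )
        field = ConcentrationField.uniform((2, 2, 2), 1e-5, f_z=1.0)
        np.testing.assert_allclose(
            drug_absorption(field, spec, 450.0), 0.23026, rtol=1e-4
        )

    def test_isomer_contrast_is_linear(self, spec):
        c = 1e-5
        pure_z = ConcentrationField.uniform((2, 2, 2), c, f_z=1.0)
        pure_e = ConcentrationField.uniform((2, 2, 2), c, f_z=0.0)
        eps_e, eps_z, _, _ = spec.at(WL)
        diff = drug_absorption(pure_e, spec, WL) - drug_absorption(pure_z, spec, WL)
        np.testing.assert_allclose(diff, LN10 * (eps_e - eps_z) * c, rtol=1e-12)


def oracle_1d_fixed_point(spec, c0, phi0, mu_a_tissue, nz, dz_cm):
    """Deterministic 1D collimated-beam attenuation + PSS fixed point."""
    eps_e, eps_z, phi_ez, phi_ze = spec.at(WL)
    kd = thermal_rate(spec.t_half_s)
    fz = np.ones(nz)
    for _ in range(500):
        mua = mu_a_tissue + LN10 * c0 * (eps_e * (1 - fz) + eps_z * fz)
        att = np.concatenate([[0.0], np.cumsum(mua * dz_cm)])
        phi_mid = phi0 * np.exp(-(att[:-1] + mua * dz_cm / 2.0))
        epf = irradiance_to_photon_flux(phi_mid, WL)
        kez = rate_constant(eps_e, phi_ez, epf)
        kze = rate_constant(eps_z, phi_ze, epf)
        fz_new = (kez + kd) / (kez + kze + kd)  # thermal side E->Z
        if np.max(np.abs(fz_new - fz)) < 1e-13:
            return fz_new
        fz = fz_new
    return fz


class TestCoupledSolve:
    def test_weak_coupling_matches_uncoupled(self, absorber_slab, spec):
        """Vanishing drug absorption: one iteration, same field as the
        uncoupled transport + PSS pipeline."""
        c0 = 1e-9  # delta-mu_a ~ 2e-5 << mu_a
        cfg = RunConfig(n_photons=50_000, rng_seed=13, wavelengths=(WL,))
        state = coupled_solve(
            absorber_slab, pencil(2.5e-3), cfg, spec, c0, tolerance=5e-3, max_iter=5
        )
        assert state.converged
        assert state.iteration <= 2
        from ppsim.photokinetics import field_kinetics

        fmap = run_mc(absorber_slab, pencil(2.5e-3), cfg)
        start = ConcentrationField.uniform(absorber_slab.dims, c0, f_z=1.0)
        ref = field_kinetics(start, fmap, spec, pss=True)
        lit = fmap.fluence[WL] > 0
        assert np.abs(state.concentrations.f_z - ref.f_z)[lit].max() < 0.02

    def test_strong_coupling_matches_1d_oracle(self, absorber_slab, spec):
        c0 = 1e-4
        cfg = RunConfig(n_photons=100_000, rng_seed=7, wavelengths=(WL,))
        state = coupled_solve(
            absorber_slab, pencil(2.5e-6), cfg, spec, c0, tolerance=5e-3, max_iter=15
        )
        assert state.converged
        fz_mc = state.concentrations.f_z[10, 10, :]
        fz_ref = oracle_1d_fixed_point(spec, c0, 1e-3, 0.1, 40, 0.025)
        assert np.max(np.abs(fz_mc - fz_ref) / fz_ref) < 0.05

    def test_self_shielding_monotone_light_driven_isomer(self, absorber_slab, spec):
        """The light-built isomer fraction decreases monotonically with
        depth once drug self-shielding is in play (blue drives Z->E here,
        so f_E must fall with z)."""
        cfg = RunConfig(n_photons=100_000, rng_seed=8, wavelengths=(WL,))
        state = coupled_solve(
            absorber_slab, pencil(2.5e-6), cfg, spec, 1e-4, tolerance=5e-3, max_iter=15
        )
        f_e = 1.0 - state.concentrations.f_z[10, 10, :]
        assert np.all(np.diff(f_e) <= 1e-9)

    def test_initial_composition_does_not_matter_at_pss(self, absorber_slab, spec):
        cfg = RunConfig(n_photons=50_000, rng_seed=9, wavelengths=(WL,))
        tol = 5e-3
        a = coupled_solve(
            absorber_slab, pencil(2.5e-4), cfg, spec,
            ConcentrationField.uniform(absorber_slab.dims, 1e-5, f_z=1.0),
            tolerance=tol, max_iter=10,
        )
        b = coupled_solve(
            absorber_slab, pencil(2.5e-4), cfg, spec,
            ConcentrationField.uniform(absorber_slab.dims, 1e-5, f_z=0.0),
            tolerance=tol, max_iter=10,
        )
        assert np.abs(a.concentrations.f_z - b.concentrations.f_z).max() < 2 * tol

    def test_tolerance_below_mc_noise_refused(self, medium_factory, spec):
        """A tolerance tighter than the MC noise floor of f_Z is rejected."""
        cls = medium_factory(0.5, 50.0, g=0.9, wavelengths=(WL,))
        noisy = build_layered_slab([(cls, 5000.0)], (10, 10, 10), (500.0,) * 3)
        cfg = RunConfig(n_photons=200, rng_seed=10, wavelengths=(WL,))
        src = SourceSpec(
            kind="pencil", position_um=(2500.0, 2500.0, 0.5), power_w={WL: 1e-4}
        )
        with pytest.raises(ValueError, match="noise floor"):
            coupled_solve(noisy, src, cfg, spec, 1e-5, tolerance=1e-9, max_iter=3)

    def test_nonconvergence_reported_honestly(self, absorber_slab, spec):
        cfg = RunConfig(n_photons=50_000, rng_seed=11, wavelengths=(WL,))
        state = coupled_solve(
            absorber_slab, pencil(2.5e-6), cfg, spec, 1e-4,
            tolerance=5e-3, max_iter=1,
        )
        assert not state.converged
        assert len(state.history) == 1


class TestTimeMarchedSolve:
    def test_zero_horizon_returns_initial_state(self, absorber_slab, spec):
        cfg = RunConfig(n_photons=1000, rng_seed=1, wavelengths=(WL,))
        states = time_marched_solve(
            absorber_slab, pencil(1e-3), cfg, spec, 1e-5, dt=1.0, horizon=0.0
        )
        assert len(states) == 1
        np.testing.assert_allclose(states[0].concentrations.f_z, 1.0)

    def test_dark_source_is_pure_thermal_relaxation(self, absorber_slab, spec):
        cfg = RunConfig(n_photons=1000, rng_seed=2, wavelengths=(WL,))
        dark = SourceSpec(
            kind="pencil", position_um=(5000.0, 5000.0, 0.5), power_w={WL: 0.0}
        )
        c0 = ConcentrationField.uniform(absorber_slab.dims, 1e-5, f_z=0.0)
        states = time_marched_solve(
            absorber_slab, dark, cfg, spec, c0, dt=100.0, horizon=300.0
        )
        kd = thermal_rate(spec.t_half_s)
        _, cz_ref = integrate_two_state(
            1e-5, 0.0, RateConstants(0.0, 0.0, kd, "E->Z"), 300.0
        )
        np.testing.assert_allclose(states[-1].concentrations.c_z, cz_ref, rtol=1e-9)

    def test_long_horizon_agrees_with_pss_fixed_point(self, absorber_slab, spec):
        """Weak coupling: marching far past the kinetic time scale lands on
        the stationary coupled solution."""
        cfg = RunConfig(n_photons=50_000, rng_seed=3, wavelengths=(WL,))
        c0 = 1e-9
        pss = coupled_solve(
            absorber_slab, pencil(2.5e-3), cfg, spec, c0, tolerance=5e-3, max_iter=5
        )
        # kappa >~ 28/s near the surface; 10 s >> 1/kappa everywhere lit
        marched = time_marched_solve(
            absorber_slab, pencil(2.5e-3), cfg, spec, c0, dt=5.0, horizon=1000.0
        )
        lit = pss.fluence.fluence[WL] > 0
        dev = np.abs(marched[-1].concentrations.f_z - pss.concentrations.f_z)[lit]
        assert dev.max() < 0.02

    def test_step_doubling_guard_passes_in_stationary_regime(self, absorber_slab, spec):
        cfg = RunConfig(n_photons=20_000, rng_seed=4, wavelengths=(WL,))
        time_marched_solve(
            absorber_slab, pencil(2.5e-3), cfg, spec, 1e-9,
            dt=50.0, horizon=100.0, step_doubling_check=True, step_doubling_tol=0.05,
        )
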