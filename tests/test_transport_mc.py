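"""Monte Carlo transport: conservation, determinism, closed-form limits.

Heavier statistical validations at the published problem sizes live in
test_acceptance.py; here the same physics is exercised at smaller photon
counts with correspondingly looser statistical bounds.
"""

import numpy as np
import pytest

import ppsim
from ppsim.phantom import build_layered_slab
from ppsim.sources import SourceSpec
from ppsim.transport import RunConfig, combine_fluence_maps, run_mc

WL = 460.0


def slab(medium_factory, mu_a, mu_s, g=0.0, n=1.0, dims=(20, 20, 40), vox=(500.0,) * 3):
    cls = medium_factory(mu_a, mu_s, g=g, n=n, wavelengths=(WL,))
    return build_layered_slab([(cls, dims[2] * vox[2])], dims, vox)


class TestConservation:
    @pytest.mark.parametrize(
        "mu_a,mu_s,g,n",
        [
            (1.0, 0.0, 0.0, 1.0),      # pure absorber
            (0.5, 20.0, 0.8, 1.37),    # scatterer with index step at boundary
            (0.01, 50.0, 0.9, 1.4),    # roulette-heavy regime
        ],
    )
    def test_weight_audit_exact(self, medium_factory, mu_a, mu_s, g, n):
        ph = slab(medium_factory, mu_a, mu_s, g, n)
        src = SourceSpec(kind="isotropic_point", position_um=(5000.0, 5000.0, 5000.0))
        fmap = run_mc(ph, src, RunConfig(n_photons=20_000, rng_seed=3, wavelengths=(WL,)))
        assert fmap.max_audit_residual() < 1e-9

    def test_fluence_nonnegative_and_absorption_free_medium(self, medium_factory):
        """Track-length tally gives fluence even where mu_a = 0."""
        ph = slab(medium_factory, 0.0, 10.0, 0.5)
        src = SourceSpec(kind="pencil", position_um=(5000.0, 5000.0, 0.5))
        fmap = run_mc(ph, src, RunConfig(n_photons=5_000, rng_seed=4, wavelengths=(WL,)))
        assert fmap.fluence[WL].min() >= 0
        assert fmap.fluence[WL].max() > 0
        assert fmap.ledger[WL]["absorbed"] == 0.0
        assert fmap.ledger[WL]["escaped"] == pytest.approx(
            fmap.ledger[WL]["launched"]
        )


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, medium_factory):
        ph = slab(medium_factory, 0.5, 30.0, 0.85)
        src = SourceSpec(kind="led_disk", position_um=(5000.0, 5000.0, 2.0), radius_um=500.0)
        cfg = RunConfig(n_photons=10_000, rng_seed=11, wavelengths=(WL,))
        a = run_mc(ph, src, cfg)
        b = run_mc(ph, src, cfg)
        assert np.array_equal(a.fluence[WL], b.fluence[WL])
        assert a.ledger[WL] == b.ledger[WL]

    def test_different_seed_differs(self, medium_factory):
        ph = slab(medium_factory, 0.5, 30.0, 0.85)
        src = SourceSpec(kind="led_disk", position_um=(5000.0, 5000.0, 2.0), radius_um=500.0)
        a = run_mc(ph, src, RunConfig(n_photons=10_000, rng_seed=11, wavelengths=(WL,)))
        b = run_mc(ph, src, RunConfig(n_photons=10_000, rng_seed=12, wavelengths=(WL,)))
        assert not np.array_equal(a.fluence[WL], b.fluence[WL])


class TestMirrorSymmetry:
    def test_absorption_only_pencil_beams_mirror_exactly(self, medium_factory):
        """In a homogeneous absorber the photon history depends only on the
        RNG stream, so mirrored sources give exactly mirrored tallies."""
        ph = slab(medium_factory, 1.0, 0.0)
        cfg = RunConfig(n_photons=20_000, rng_seed=5, wavelengths=(WL,))
        left = run_mc(
            ph, SourceSpec(kind="pencil", position_um=(2250.0, 5000.0, 0.5)), cfg
        )
        right = run_mc(
            ph, SourceSpec(kind="pencil", position_um=(7750.0, 5000.0, 0.5)), cfg
        )
        assert np.array_equal(left.fluence[WL], right.fluence[WL][::-1, :, :])


class TestBeerLambert:
    def test_on_axis_attenuation(self, medium_factory):
        ph = slab(medium_factory, 1.0, 0.0, dims=(20, 20, 60))
        src = SourceSpec(kind="pencil", position_um=(5000.0, 5000.0, 0.5))
        fmap = run_mc(ph, src, RunConfig(n_photons=200_000, rng_seed=1, wavelengths=(WL,)))
        phi = fmap.fluence[WL][10, 10, :]
        z = (np.arange(60) + 0.5) * 0.05
        area = 0.05 * 0.05  # pencil normalized per beam cross-section voxel
        rel = phi * area / np.exp(-z) - 1
        assert np.abs(rel[z <= 2.0]).max() < 0.05


class TestSourceGeometry:
    def test_source_aimed_away_all_weight_escapes(self, medium_factory):
        ph = slab(medium_factory, 1.0, 0.0)
        src = SourceSpec(
            kind="pencil", position_um=(5000.0, 5000.0, -1000.0), direction=(0, 0, -1)
        )
        fmap = run_mc(ph, src, RunConfig(n_photons=1000, rng_seed=2, wavelengths=(WL,)))
        led = fmap.ledger[WL]
        assert led["escaped"] == pytest.approx(led["launched"])
        assert fmap.fluence[WL].max() == 0.0

    def test_power_scaling_is_linear(self, medium_factory):
        ph = slab(medium_factory, 1.0, 0.0)
        cfg = RunConfig(n_photons=5_000, rng_seed=3, wavelengths=(WL,))
        p1 = run_mc(ph, SourceSpec(kind="pencil", position_um=(5000.0, 5000.0, 0.5),
                                   power_w={WL: 1.0}), cfg)
        p2 = run_mc(ph, SourceSpec(kind="pencil", position_um=(5000.0, 5000.0, 0.5),
                                   power_w={WL: 2.5}), cfg)
        np.testing.assert_allclose(2.5 * p1.fluence[WL], p2.fluence[WL], rtol=1e-12)

    def test_combine_fluence_maps_adds(self, medium_factory):
        ph = slab(medium_factory, 1.0, 0.0)
        cfg = RunConfig(n_photons=5_000, rng_seed=3, wavelengths=(WL,))
        src = SourceSpec(kind="pencil", position_um=(5000.0, 5000.0, 0.5))
        one = run_mc(ph, src, cfg)
        two = combine_fluence_maps([one, one])
        np.testing.assert_allclose(two.fluence[WL], 2 * one.fluence[WL])
        assert two.audit_residual(WL) < 1e-9


class TestWaveguideContrast:
    def test_probe_boosts_blue_more_than_red(self):
        """Deep-target light delivery: the implanted high-index probe must
        strongly benefit blue light while red penetrates tissue anyway."""
        from ppsim.pipeline import demo_sources, target_fluence_stats

        bare = ppsim.build_rat_head_phantom((60, 60, 150), (40.0, 40.0, 40.0))
        probed = ppsim.insert_probe(bare, ppsim.ProbeSpec(depth_um=4000.0))
        cfg = ppsim.RunConfig(n_photons=40_000, rng_seed=6, wavelengths=(460.0, 620.0))
        src = demo_sources(bare)
        blue_probe, se_bp = target_fluence_stats(probed, src, cfg, 460.0, n_batches=2)
        blue_bare, se_bb = target_fluence_stats(bare, src, cfg, 460.0, n_batches=2)
        red_probe, _ = target_fluence_stats(probed, src, cfg, 620.0, n_batches=2)
        red_bare, _ = target_fluence_stats(bare, src, cfg, 620.0, n_batches=2)
        assert blue_probe > blue_bare
        blue_gain = blue_probe / blue_bare
        red_gain = red_probe / red_bare
        assert blue_gain > red_gain
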