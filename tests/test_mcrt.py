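"""Monte Carlo transport: elementary sampling, conservation, analytic limits."""

import math

import numpy as np
import pytest

from faruvc import mcrt
from faruvc.exceptions import DomainError
from faruvc.mcrt import (
    FluenceProfile,
    PhotonState,
    SkinModel,
    fluence_at_depth,
    fluence_ratio,
    fresnel_reflectance,
    propagate_photon,
    sample_free_path,
    sample_scatter,
    simulate_fluence,
)
from faruvc.spectra import SpectralDistribution

UNIT_SRC = SpectralDistribution([200.0, 400.0], [1.0, 1.0], "absolute")


class TestSampleFreePath:
    def test_closed_form(self):
        assert sample_free_path(2.0, math.exp(-1.0)) == pytest.approx(0.5)

    def test_mean_matches_analytic(self):
        rng = np.random.default_rng(1)
        mu_t = 3.0
        draws = np.array([sample_free_path(mu_t, u) for u in rng.random(100_000)])
        sem = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 1.0 / mu_t) < 3 * sem

    def test_u_near_one_gives_vanishing_step(self):
        assert sample_free_path(1.0, 1.0 - 1e-12) < 1e-11

    def test_vacuum_gives_infinite_step(self):
        assert math.isinf(sample_free_path(0.0, 0.5))


class TestSampleScatter:
    def test_isotropic_limit(self):
        # g = 0: cos(theta) = 2u - 1, so u = 0.5 leaves direction orthogonal
        out = sample_scatter([0.0, 0.0, 1.0], 0.0, 0.5, 0.0)
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_mean_cosine_equals_g(self):
        rng = np.random.default_rng(2)
        g = 0.8
        n = 100_000
        cos_t = np.array(
            [sample_scatter([0.0, 0.0, 1.0], g, u, 0.0)[2] for u in rng.random(n)]
        )
        sem = cos_t.std(ddof=1) / math.sqrt(n)
        assert abs(cos_t.mean() - g) < 3 * sem

    def test_output_normalized(self):
        rng = np.random.default_rng(3)
        d = np.array([0.3, -0.5, math.sqrt(1 - 0.09 - 0.25)])
        for _ in range(200):
            d = sample_scatter(d, 0.9, rng.random(), rng.random())
            assert abs(np.linalg.norm(d) - 1.0) < 1e-9


class TestFresnel:
    def test_normal_incidence_air_glass(self):
        assert fresnel_reflectance(1.0, 1.5, 1.0) == pytest.approx(0.04)

    def test_matched_boundary(self):
        assert fresnel_reflectance(1.38, 1.38, 0.7) == 0.0

    def test_total_internal_reflection(self):
        # critical angle for 1.38 -> 1.0: sin = 1/1.38, cos ~ 0.689
        assert fresnel_reflectance(1.38, 1.0, 0.5) == 1.0

    def test_grazing_incidence_approaches_one(self):
        assert fresnel_reflectance(1.0, 1.38, 1e-3) > 0.95


class TestPropagatePhoton:
    def test_absorption_only_straight_path(self):
        model = SkinModel.homogeneous(1.0, 0.0, thickness_um=5000.0)
        rng = np.random.default_rng(5)
        led = propagate_photon(
            PhotonState([0, 0, 0], [0, 0, 1], 1.0, 300.0), model, rng
        )
        # no scattering: photon stays on the z axis and deposits everything
        assert led["final_position"][0] == 0.0 and led["final_position"][1] == 0.0
        assert led["deposited"] == pytest.approx(1.0)

    def test_weight_ledger_closes_per_photon(self, skin_preset):
        rng = np.random.default_rng(6)
        for wavelength in (222.0, 300.0, 380.0):
            for _ in range(50):
                led = propagate_photon(
                    PhotonState([0, 0, 0], [0, 0, 1], 1.0, wavelength),
                    skin_preset, rng,
                )
                closure = led["deposited"] + led["escaped"] + led["roulette_net"]
                assert closure == pytest.approx(led["launched"], abs=1e-9)

    def test_mean_penetration_depth_is_inverse_mu_a(self):
        mu_a = 2.0  # mm^-1
        model = SkinModel.homogeneous(mu_a, 0.0, thickness_um=20_000.0)
        rng = np.random.default_rng(7)
        depths = []
        for _ in range(3000):
            led = propagate_photon(
                PhotonState([0, 0, 0], [0, 0, 1], 1.0, 300.0), model, rng
            )
            depths.append(led["final_position"][2] * 1e-3)  # mm
        depths = np.asarray(depths)
        sem = depths.std(ddof=1) / math.sqrt(depths.size)
        assert abs(depths.mean() - 1.0 / mu_a) < 3 * sem


class TestSimulateFluence:
    def test_beer_lambert_profile(self):
        mu_a_um = 1e-3  # 1 mm^-1
        model = SkinModel.homogeneous(1.0, 0.0, thickness_um=2000.0)
        prof = simulate_fluence(model, UNIT_SRC, 20_000, depth_bin_um=100.0, seed=11)
        z0, z1 = prof.depth_edges_um[:-1], prof.depth_edges_um[1:]
        expected = (np.exp(-mu_a_um * z0) - np.exp(-mu_a_um * z1)) / (
            mu_a_um * (z1 - z0)
        )
        resid = np.abs(prof.fluence[:, 0] - expected)
        assert np.all(resid <= 3 * np.maximum(prof.fluence_sem[:, 0], 1e-12))
        # fluence at 1 mm is e^-1 of the surface bin value
        ratio = prof.fluence[10, 0] / prof.fluence[0, 0]
        assert ratio == pytest.approx(math.exp(-1.0), rel=0.05)

    def test_tally_closure_every_wavelength(self, skin_preset, lamp_filtered):
        prof = simulate_fluence(
            skin_preset, lamp_filtered, 1000, depth_bin_um=20.0, seed=12,
            max_depth_um=200.0,
        )
        closure = prof.reflected + prof.transmitted + prof.absorbed
        assert np.abs(closure - 1.0).max() < 1e-6
        assert np.all(prof.fluence >= 0.0)

    def test_seed_determinism(self):
        model = SkinModel.homogeneous(1.0, 5.0, g=0.9, thickness_um=1000.0)
        a = simulate_fluence(model, UNIT_SRC, 2000, 50.0, seed=13)
        b = simulate_fluence(model, UNIT_SRC, 2000, 50.0, seed=13)
        np.testing.assert_array_equal(a.fluence, b.fluence)
        np.testing.assert_array_equal(a.reflected, b.reflected)

    def test_different_seeds_agree_within_mc_error(self):
        model = SkinModel.homogeneous(1.0, 5.0, g=0.9, thickness_um=1000.0)
        a = simulate_fluence(model, UNIT_SRC, 20_000, 100.0, seed=14)
        b = simulate_fluence(model, UNIT_SRC, 20_000, 100.0, seed=15)
        sigma = np.sqrt(a.fluence_sem**2 + b.fluence_sem**2)
        assert np.all(np.abs(a.fluence - b.fluence) <= 4 * np.maximum(sigma, 1e-12))

    def test_monotone_decay_in_homogeneous_slab(self):
        model = SkinModel.homogeneous(2.0, 10.0, g=0.9, thickness_um=2000.0,
                                      tissue_n=1.38)
        prof = simulate_fluence(model, UNIT_SRC, 20_000, 100.0, seed=16)
        f = prof.fluence[:, 0]
        tol = 3 * np.sqrt(prof.fluence_sem[1:, 0] ** 2 + prof.fluence_sem[:-1, 0] ** 2)
        assert np.all(np.diff(f[1:]) <= tol[1:])

    def test_grid_refinement_stable(self):
        model = SkinModel.homogeneous(1.0, 5.0, g=0.9, thickness_um=1000.0)
        coarse = simulate_fluence(model, UNIT_SRC, 20_000, 100.0, seed=17)
        fine = simulate_fluence(model, UNIT_SRC, 20_000, 50.0, seed=18)
        band = (200.0, 400.0)
        depth = 450.0
        fc = fluence_at_depth(coarse, depth, band)
        ff = fluence_at_depth(fine, depth, band)
        # halving the bin width moves the marker value by less than the
        # combined statistical + discretisation scale of the bin
        assert abs(fc - ff) / fc < 0.05

    def test_rejects_non_overlapping_source(self, skin_preset):
        src = SpectralDistribution([500.0, 600.0], [1.0, 1.0], "absolute")
        with pytest.raises(DomainError):
            simulate_fluence(skin_preset, src, 1000, seed=19)


@pytest.fixture(scope="module")
def beer_profile():
    model = SkinModel.homogeneous(1.0, 0.0, thickness_um=2000.0)
    return simulate_fluence(model, UNIT_SRC, 5000, 100.0, seed=20)


class TestFluenceQueries:

    def test_surface_bin_is_maximum(self, beer_profile):
        f = [
            fluence_at_depth(beer_profile, z, (200.0, 400.0))
            for z in beer_profile.depth_centers_um
        ]
        assert np.argmax(f) == 0

    def test_zero_width_band(self, beer_profile):
        assert fluence_at_depth(beer_profile, 50.0, (300.0, 300.0)) == 0.0

    def test_marker_outside_span_rejected(self, beer_profile):
        with pytest.raises(DomainError):
            fluence_at_depth(beer_profile, 5000.0, (200.0, 400.0))

    def test_identical_profiles_ratio_one(self, beer_profile):
        r, sigma = fluence_ratio(beer_profile, beer_profile, 150.0, (200.0, 400.0))
        assert r == pytest.approx(1.0)

    def test_ratio_invariant_to_common_source_rescale(self, beer_profile):
        scaled = FluenceProfile(
            beer_profile.depth_edges_um, beer_profile.wavelengths_nm,
            beer_profile.fluence, beer_profile.fluence_sem,
            beer_profile.source_values * 7.0, beer_profile.photons_per_wavelength,
            beer_profile.seed, beer_profile.reflected, beer_profile.transmitted,
            beer_profile.absorbed,
        )
        r0, _ = fluence_ratio(beer_profile, beer_profile, 150.0, (200.0, 400.0))
        r1, _ = fluence_ratio(scaled, scaled, 150.0, (200.0, 400.0))
        assert r1 == pytest.approx(r0)

    def test_basal_222_far_below_300_for_equal_power(self, skin_preset):
        src = UNIT_SRC
        prof = simulate_fluence(
            skin_preset, src, 3000, 10.0, seed=21, max_depth_um=120.0
        )
        basal = skin_preset.markers["basal_layer"]
        f222 = fluence_at_depth(prof, basal, (220.0, 224.0))
        f300 = fluence_at_depth(prof, basal, (298.0, 302.0))
        assert f222 < 0.01 * f300
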