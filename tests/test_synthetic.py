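"""Synthetic generators: lamp spectra, skin presets, yellowing ground truth."""

import math

import numpy as np
import pytest

from faruvc import colorimetry, synthetic
from faruvc.exceptions import DomainError
from faruvc.spectra import band_irradiance
from faruvc.synthetic import (
    LampSpecification,
    YellowingKinetics,
    fit_decay_time,
    fit_dose_response,
    make_lamp_spectrum,
    make_reflectance_series,
    make_skin_preset,
    recover_amplitudes,
)


class TestLampSpectrum:
    def test_unfiltered_peaks_at_222_with_more_sideband(
        self, lamp_unfiltered, lamp_filtered
    ):
        w = lamp_unfiltered.wavelengths_nm
        assert w[np.argmax(lamp_unfiltered.values)] == 222.0
        frac_u = band_irradiance(lamp_unfiltered, 230, 280) / band_irradiance(
            lamp_unfiltered, 200, 400
        )
        frac_f = band_irradiance(lamp_filtered, 230, 280) / band_irradiance(
            lamp_filtered, 200, 400
        )
        assert frac_u > frac_f

    def test_suppression_factor_exact(self, lamp_unfiltered, lamp_filtered):
        ratio = band_irradiance(lamp_filtered, 230, 280) / band_irradiance(
            lamp_unfiltered, 230, 280
        )
        assert ratio == pytest.approx(synthetic.FILTER_SUPPRESSION, rel=1e-6)
        additional = make_lamp_spectrum(filtered="additional")
        ratio2 = band_irradiance(additional, 230, 280) / band_irradiance(
            lamp_unfiltered, 230, 280
        )
        assert ratio2 == pytest.approx(synthetic.ADDITIONAL_SUPPRESSION, rel=1e-6)

    def test_pure_gaussian_integral_analytic(self):
        spec = LampSpecification(
            long_wavelength_lines=(), continuum=0.0, grid_pitch_nm=0.1
        )
        s = make_lamp_spectrum(spec, filtered="unfiltered")
        sigma = spec.peak_fwhm_nm / (2 * math.sqrt(2 * math.log(2)))
        analytic = sigma * math.sqrt(2 * math.pi)  # peak height 1
        assert band_irradiance(s, 200, 400) == pytest.approx(analytic, rel=1e-4)

    def test_invalid_spec_rejected(self):
        with pytest.raises(DomainError):
            LampSpecification(long_wavelength_lines=((250.0, 1.5),))
        with pytest.raises(DomainError):
            make_lamp_spectrum(filtered="double")


class TestSkinPreset:
    def test_default_structure(self, skin_preset):
        assert len(skin_preset.layers) == 5
        assert skin_preset.markers["basal_layer"] == 100.0
        assert skin_preset.markers["top_of_epidermis"] == 20.0
        # basal marker sits at the bottom of the living epidermis
        assert skin_preset.boundaries_um[2] == 100.0

    def test_epidermal_absorption_stronger_at_222_than_300(self, skin_preset):
        for layer in skin_preset.layers[:2]:
            assert layer.mu_a_at(222.0) > layer.mu_a_at(300.0)

    def test_round_trip_through_config_file(self, skin_preset, tmp_path):
        path = tmp_path / "preset.toml"
        skin_preset.to_toml(path)
        back = synthetic.SkinModel.from_toml(path)
        assert back.markers == skin_preset.markers
        assert len(back.layers) == len(skin_preset.layers)
        for a, b in zip(back.layers, skin_preset.layers):
            np.testing.assert_allclose(a.mu_a_mm, b.mu_a_mm, rtol=1e-12)
            np.testing.assert_allclose(a.mu_s_mm, b.mu_s_mm, rtol=1e-12)

    def test_unknown_preset_rejected(self):
        with pytest.raises(DomainError):
            make_skin_preset("stratum-lucidum-7layer")


NOISELESS = YellowingKinetics(noise_sd=0.0)
TIMES = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0]


class TestReflectanceSeries:
    def test_subthreshold_dose_indistinguishable_from_zero(self):
        k = YellowingKinetics(noise_sd=0.002)
        series = make_reflectance_series(1500.0, TIMES, k, seed=3)
        deltas = colorimetry.delta_series(series)
        # threshold sits above 1500: response is pure measurement noise
        assert max(abs(d.delta_b) for d in deltas) < 0.45

    def test_larger_dose_larger_delta_b(self):
        d6 = colorimetry.delta_series(
            make_reflectance_series(6000.0, [0.0, 1.0], NOISELESS)
        )
        d12 = colorimetry.delta_series(
            make_reflectance_series(12000.0, [0.0, 1.0], NOISELESS)
        )
        assert d12[1].delta_b > d6[1].delta_b > 0

    def test_baseline_exact_zero_without_noise(self):
        series = make_reflectance_series(18000.0, [0.0, 1.0], NOISELESS)
        d = colorimetry.delta_series(series)
        assert d[0].delta_b == 0.0 and d[0].delta_a == 0.0

    def test_delta_b_non_increasing_after_onset(self):
        series = make_reflectance_series(12000.0, TIMES, NOISELESS)
        db = [d.delta_b for d in colorimetry.delta_series(series)][1:]
        assert all(a >= b for a, b in zip(db, db[1:]))

    def test_tape_strip_reduces_delta_b(self):
        stripped = make_reflectance_series(
            12000.0, TIMES, NOISELESS, tape_strip_at_h=1.0
        )
        plain = make_reflectance_series(12000.0, TIMES, NOISELESS)
        db_s = colorimetry.delta_series(stripped)
        db_p = colorimetry.delta_series(plain)
        assert db_s[2].delta_b < db_p[2].delta_b

    def test_seed_determinism(self):
        a = make_reflectance_series(6000.0, TIMES, seed=9)
        b = make_reflectance_series(6000.0, TIMES, seed=9)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.reflectance, mb.reflectance)

    def test_times_must_include_baseline(self):
        with pytest.raises(DomainError):
            make_reflectance_series(6000.0, [1.0, 2.0])


class TestParameterRecovery:
    def test_tau_recovered_to_1e6_noise_free(self):
        k = YellowingKinetics(noise_sd=0.0, tau_h=6.0)
        series = make_reflectance_series(12000.0, TIMES, k)
        assert fit_decay_time(series) == pytest.approx(6.0, rel=1e-6)

    def test_tau_recovery_other_parameterisations(self):
        for tau in (2.0, 10.0):
            k = YellowingKinetics(noise_sd=0.0, tau_h=tau, A_max=0.3)
            series = make_reflectance_series(9000.0, TIMES, k)
            assert fit_decay_time(series) == pytest.approx(tau, rel=1e-6)

    def test_d0_recovered_within_5pct_across_doses(self):
        k = YellowingKinetics(noise_sd=0.0)
        doses = np.array([4000.0, 6000.0, 12000.0, 18000.0])
        amps = []
        t1 = 0.5
        for d in doses:
            series = make_reflectance_series(d, [0.0, t1], k)
            _, a = recover_amplitudes(series)
            amps.append(a[0] * math.exp(t1 / k.tau_h))  # back-correct decay
        a_max, d0 = fit_dose_response(doses, np.array(amps), k.threshold_dose_mJ_cm2)
        assert d0 == pytest.approx(k.D0_mJ_cm2, rel=0.05)
        assert a_max == pytest.approx(k.A_max, rel=0.05)

    def test_amplitude_inversion_exact(self):
        k = YellowingKinetics(noise_sd=0.0)
        series = make_reflectance_series(18000.0, [0.0, 1.0], k)
        _, amps = recover_amplitudes(series)
        expected = k.amplitude(18000.0) * math.exp(-1.0 / k.tau_h)
        assert amps[0] == pytest.approx(expected, rel=1e-9)
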