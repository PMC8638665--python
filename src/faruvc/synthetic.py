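"""Synthetic inputs with known ground truth: lamp spectra, skin presets,
and reflectance time series.

No numeric tables exist for the study's lamp spectra, skin optics, or
reflectance measurements, so every pipeline input is emulated here with an
explicit parameterisation:

* **Lamp**: a KrCl excimer spectrum — Gaussian principal line at 222 nm,
  weak Gaussian side emissions in the 230-280 nm region, and a faint flat
  continuum.  "filtered" multiplies the 230-280 nm content by 1e-2 and
  "additional" filtering by 1e-4, mimicking the short-pass filtering that
  suppresses the biologically hazardous longer UVC wavelengths.
* **Skin preset**: the packaged 5-layer UV optics stand-in (see
  ``presets/skin_default.toml``).
* **Yellowing**: a phenomenological model of the observed dose-dependent,
  stratum-corneum-confined skin yellowing — a blue-band chromophore whose
  amplitude saturates with dose above a threshold,
  A(dose) = A_max (1 - exp(-(dose - threshold)/D0)), and clears
  exponentially with time constant tau_h; tape stripping removes a fraction
  of the remaining chromophore.  No mechanism is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DomainError
from .colorimetry import ReflectanceMeasurement
from .mcrt import SkinModel
from .spectra import SpectralDistribution, normalize_to_peak

__all__ = [
    "LampSpecification",
    "YellowingKinetics",
    "make_lamp_spectrum",
    "make_skin_preset",
    "make_reflectance_series",
    "chromophore_band",
    "recover_amplitudes",
    "fit_decay_time",
    "fit_dose_response",
]

SUPPRESSION_BAND_NM = (230.0, 280.0)
FILTER_SUPPRESSION = 1e-2
ADDITIONAL_SUPPRESSION = 1e-4


@dataclass(frozen=True)
class LampSpecification:
    """Parametric KrCl-like lamp emission model (relative units)."""

    peak_nm: float = 222.0
    peak_fwhm_nm: float = 2.0
    long_wavelength_lines: tuple[tuple[float, float], ...] = (
        (240.0, 0.004),
        (248.0, 0.006),
        (258.0, 0.008),
        (270.0, 0.003),
    )
    line_fwhm_nm: float = 8.0
    continuum: float = 1e-6
    grid_lo_nm: float = 200.0
    grid_hi_nm: float = 400.0
    grid_pitch_nm: float = 0.5

    def __post_init__(self) -> None:
        amps = [a for _, a in self.long_wavelength_lines]
        if any(not 0 <= a <= 1 for a in amps):
            raise DomainError("line amplitudes must lie in [0, 1]")
        if amps and max(amps) >= 1.0:
            raise DomainError("side lines must stay below the principal peak")
        if self.peak_fwhm_nm <= 0 or self.grid_pitch_nm <= 0:
            raise DomainError("widths and pitch must be positive")


def _gauss(lam: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def make_lamp_spectrum(
    spec: LampSpecification = LampSpecification(),
    filtered: str = "filtered",
) -> SpectralDistribution:
    """Build a peak-normalised lamp spectrum.

    ``filtered`` is one of ``"unfiltered"``, ``"filtered"`` (230-280 nm
    content x 1e-2) or ``"additional"`` (x 1e-4).  Construction is
    deterministic — the lamp model has no noise term.
    """
    if filtered not in ("unfiltered", "filtered", "additional"):
        raise DomainError("filtered must be 'unfiltered', 'filtered' or 'additional'")
    n = int(round((spec.grid_hi_nm - spec.grid_lo_nm) / spec.grid_pitch_nm)) + 1
    lam = np.linspace(spec.grid_lo_nm, spec.grid_hi_nm, n)
    values = _gauss(lam, spec.peak_nm, spec.peak_fwhm_nm).astype(float)
    side = np.zeros_like(values)
    for center, amp in spec.long_wavelength_lines:
        side += amp * _gauss(lam, center, spec.line_fwhm_nm)
    side += spec.continuum
    if filtered == "filtered":
        factor = FILTER_SUPPRESSION
    elif filtered == "additional":
        factor = ADDITIONAL_SUPPRESSION
    else:
        factor = 1.0
    lo, hi = SUPPRESSION_BAND_NM
    in_band = (lam >= lo) & (lam <= hi)
    side[in_band] *= factor
    values += side
    return normalize_to_peak(SpectralDistribution(lam, values, "relative"))


def make_skin_preset(name: str = "default-5layer") -> SkinModel:
    """Load a packaged skin-optics preset by name."""
    presets = {"default-5layer": "skin_default.toml"}
    if name not in presets:
        raise DomainError(f"unknown skin preset {name!r}; have {sorted(presets)}")
    with resources.as_file(
        resources.files("faruvc.presets") / presets[name]
    ) as path:
        return SkinModel.from_toml(path)


# ---------------------------------------------------------------------------
# reflectance time series with yellowing ground truth

@dataclass(frozen=True)
class YellowingKinetics:
    """Phenomenological dose-response and clearance of the skin yellowing.

    ``A_max`` is the saturation chromophore amplitude (optical-density-like,
    dimensionless), ``D0`` the dose scale of the saturating response
    (mJ cm^-2), ``threshold_dose`` the dose below which no response occurs,
    ``tau_h`` the exponential clearance time constant (hours; the default
    makes a 6000 mJ cm^-2 response fall below the noise floor by 24 h),
    ``strip_factor`` the chromophore fraction removed by one tape strip and
    ``noise_sd`` the per-band Gaussian reflectance noise of the instrument.
    """

    A_max: float = 0.5
    D0_mJ_cm2: float = 6000.0
    tau_h: float = 6.0
    threshold_dose_mJ_cm2: float = 3000.0
    strip_factor: float = 0.8
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if min(self.A_max, self.D0_mJ_cm2, self.tau_h) <= 0:
            raise DomainError("A_max, D0 and tau_h must be positive")
        if self.threshold_dose_mJ_cm2 < 0 or self.noise_sd < 0:
            raise DomainError("threshold dose and noise must be non-negative")
        if not 0 <= self.strip_factor <= 1:
            raise DomainError("strip_factor must lie in [0, 1]")

    def amplitude(self, dose_mJ_cm2: float) -> float:
        """Saturating dose response A(dose); zero at or below threshold."""
        excess = dose_mJ_cm2 - self.threshold_dose_mJ_cm2
        if excess <= 0:
            return 0.0
        return self.A_max * (1.0 - math.exp(-excess / self.D0_mJ_cm2))


_VIS_GRID = np.arange(400.0, 701.0, 10.0)


def baseline_reflectance(wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """Smooth pale-skin-like reflectance rising from 0.30 (400 nm) to 0.60 (700 nm)."""
    lam = _VIS_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    x = np.clip((lam - 400.0) / 300.0, 0.0, 1.0)
    return 0.30 + 0.30 * x * x * (3.0 - 2.0 * x)  # smoothstep


def chromophore_band(wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """Normalised blue-band absorber shape (Gaussian at 440 nm, sigma 50 nm).

    Reflectance under chromophore amplitude A is
    R(lambda) = R0(lambda) * exp(-A * B(lambda)); suppressing blue
    reflectance raises b* (yellowing) while leaving a* nearly unchanged.
    """
    lam = _VIS_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    return np.exp(-0.5 * ((lam - 440.0) / 50.0) ** 2)


_RED_BAND_CENTER = 555.0  # green absorber (haemoglobin-like) raises a*


def make_reflectance_series(
    dose_mJ_cm2: float,
    times_h: Sequence[float],
    kinetics: YellowingKinetics = YellowingKinetics(),
    tape_strip_at_h: float | None = None,
    seed: int = 0,
    site: str = "site",
    redness_amplitude: float = 0.0,
) -> list[ReflectanceMeasurement]:
    """Generate a seeded reflectance time series for one exposure site.

    ``times_h`` must include 0 (the pre-irradiation baseline, chromophore
    amplitude zero); later times carry
    A(dose) exp(-t/tau_h), multiplied by (1 - strip_factor) from
    ``tape_strip_at_h`` onward.  ``redness_amplitude`` adds a green-band
    absorber producing an erythema-like delta-a elevation (zero by default;
    the study observed none).  Gaussian noise of sd ``noise_sd`` is added
    per band, clipped to physical reflectance.
    """
    times = list(times_h)
    if dose_mJ_cm2 < 0:
        raise DomainError("dose must be non-negative")
    if 0.0 not in times:
        raise DomainError("times_h must include the t=0 baseline")
    if sorted(times) != times:
        raise DomainError("times_h must be ascending")
    rng = np.random.default_rng(seed)
    lam = _VIS_GRID
    r0 = baseline_reflectance(lam)
    band = chromophore_band(lam)
    red_band = np.exp(-0.5 * ((lam - _RED_BAND_CENTER) / 25.0) ** 2)
    a0 = kinetics.amplitude(dose_mJ_cm2)
    out = []
    for t in times:
        if t == 0.0:
            amp = 0.0
            red = 0.0
        else:
            amp = a0 * math.exp(-t / kinetics.tau_h)
            red = redness_amplitude * math.exp(-t / kinetics.tau_h)
            if tape_strip_at_h is not None and t >= tape_strip_at_h:
                amp *= 1.0 - kinetics.strip_factor
        r = r0 * np.exp(-amp * band - red * red_band)
        if kinetics.noise_sd > 0:
            r = r + rng.normal(0.0, kinetics.noise_sd, size=lam.size)
        out.append(
            ReflectanceMeasurement(lam, np.clip(r, 0.0, 1.2), float(t), site)
        )
    return out


# ---------------------------------------------------------------------------
# ground-truth recovery (used to validate the generator)

def recover_amplitudes(
    series: Sequence[ReflectanceMeasurement],
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the chromophore model: amplitude per post-baseline time point.

    Uses the known band shape B: with R(t) = R0 exp(-A(t) B), the least
    squares projection of -ln(R(t)/R0) onto B recovers A(t) exactly in the
    noise-free case.  Returns (times_h, amplitudes) for t > 0.
    """
    if not series or series[0].time_h != 0:
        raise DomainError("series must start with the t=0 baseline")
    lam = series[0].wavelengths_nm
    r0 = series[0].reflectance
    band = chromophore_band(lam)
    bb = float(np.dot(band, band))
    times, amps = [], []
    for m in series[1:]:
        with np.errstate(divide="ignore"):
            c = -np.log(np.maximum(m.reflectance, 1e-12) / np.maximum(r0, 1e-12))
        times.append(m.time_h)
        amps.append(float(np.dot(c, band) / bb))
    return np.asarray(times), np.asarray(amps)


def fit_decay_time(series: Sequence[ReflectanceMeasurement]) -> float:
    """Recover the clearance time constant tau_h from one series.

    Linear least squares on log amplitude versus time; exact (to float
    precision) for a noise-free single-exponential series.
    """
    times, amps = recover_amplitudes(series)
    mask = amps > 0
    if int(mask.sum()) < 2:
        raise DomainError("need >= 2 positive-amplitude time points to fit tau")
    slope = np.polyfit(times[mask], np.log(amps[mask]), 1)[0]
    if slope >= 0:
        raise DomainError("amplitudes do not decay; cannot fit tau")
    return float(-1.0 / slope)


def fit_dose_response(
    doses_mJ_cm2: np.ndarray,
    amplitudes: np.ndarray,
    threshold_dose_mJ_cm2: float,
) -> tuple[float, float]:
    """Fit A(dose) = A_max (1 - exp(-(dose-threshold)/D0)); returns (A_max, D0)."""
    doses = np.asarray(doses_mJ_cm2, float)
    amps = np.asarray(amplitudes, float)
    if doses.size < 2:
        raise DomainError("need >= 2 doses to fit the dose response")

    def model(d, a_max, d0):
        return a_max * (1.0 - np.exp(-np.maximum(d - threshold_dose_mJ_cm2, 0.0) / d0))

    p0 = (max(amps.max(), 1e-6), max(doses.max() - threshold_dose_mJ_cm2, 1.0))
    popt, _ = curve_fit(model, doses, amps, p0=p0, maxfev=20_000)
    return float(popt[0]), float(popt[1])
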