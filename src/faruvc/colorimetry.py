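"""Reflectance colorimetry: CIELAB conversion and skin-response deltas.

A reflectance spectrophotometer reading of skin is reduced to CIE 1976
L*a*b* coordinates: L* lightness (0 black - 100 white), a* green-to-red
(the erythema axis), b* blue-to-yellow (the yellowing axis).  Skin response
to irradiation is quantified as delta-a(t) = a*(t) - a*(0) and likewise
delta-b, relative to the pre-irradiation baseline; a positive delta-b is a
yellowing of the site.

The tristimulus integration uses shipped illuminant x observer tables
(default: D65 with the CIE 1964 10-degree observer, typical for handheld
sphere instruments; specular component treated as included).  Because the
white point is computed from the same tables, a perfect reflecting diffuser
maps to L* = 100, a* = b* = 0 identically, and any spectrally flat sample is
exactly neutral.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .exceptions import DomainError

__all__ = [
    "ReflectanceMeasurement",
    "LabColor",
    "ColorDelta",
    "ResponseThresholds",
    "reflectance_to_lab",
    "delta_series",
    "classify_response",
]

_DELTA = 6.0 / 29.0


def _load_table(name: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    path = resources.files("faruvc.data") / name
    header: list[str] = []
    rows: list[list[float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "," in line and "wavelength_nm" in line:
                    header = [c.strip() for c in line.lstrip("# ").split(",")]
                continue
            rows.append([float(x) for x in line.split(",")])
    data = np.asarray(rows)
    cols = {h: data[:, i] for i, h in enumerate(header)}
    return cols.pop("wavelength_nm"), cols


_CMF_WL, _CMF = _load_table("cie_observers.csv")
_ILL_WL, _ILL = _load_table("illuminants.csv")

OBSERVERS = {
    "10deg": ("x10", "y10", "z10"),
    "2deg": ("x2", "y2", "z2"),
}
ILLUMINANTS = tuple(_ILL.keys())


@dataclass(frozen=True)
class ReflectanceMeasurement:
    """A timestamped visible-range reflectance spectrum of one skin site."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    time_h: float
    site: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if w.ndim != 1 or w.size < 2 or not np.all(np.diff(w) > 0):
            raise DomainError("wavelengths must be a strictly ascending grid")
        if r.shape != w.shape:
            raise DomainError("reflectance and wavelengths differ in length")
        # gloss can push reflectance marginally above 1
        if np.any(r < 0) or np.any(r > 1.2):
            raise DomainError("reflectance must lie in [0, 1.2]")
        if self.time_h < 0:
            raise DomainError("time_h must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class LabColor:
    L_star: float
    a_star: float
    b_star: float


@dataclass(frozen=True)
class ColorDelta:
    """Change in CIELAB coordinates relative to the pre-irradiation baseline."""

    time_h: float
    delta_L: float
    delta_a: float
    delta_b: float


def _f(t: np.ndarray) -> np.ndarray:
    # CIELAB cube-root compression with the linear segment below (6/29)^3
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def reflectance_to_lab(
    m: ReflectanceMeasurement,
    illuminant: str = "D65",
    observer: str = "10deg",
) -> LabColor:
    """Convert a reflectance spectrum to CIELAB under a shipped weight set.

    The reflectance is linearly interpolated onto the 10 nm weight grid
    (400-700 nm); beyond the measured range the edge values are held.
    """
    if illuminant not in _ILL:
        raise DomainError(f"unknown illuminant {illuminant!r}; have {ILLUMINANTS}")
    if observer not in OBSERVERS:
        raise DomainError(f"unknown observer {observer!r}; have {tuple(OBSERVERS)}")
    S = _ILL[illuminant]
    xb, yb, zb = (_CMF[c] for c in OBSERVERS[observer])
    R = np.interp(_CMF_WL, m.wavelengths_nm, m.reflectance)
    k = 100.0 / np.sum(S * yb)
    X = k * np.sum(S * xb * R)
    Y = k * np.sum(S * yb * R)
    Z = k * np.sum(S * zb * R)
    Xn = k * np.sum(S * xb)
    Yn = 100.0
    Zn = k * np.sum(S * zb)
    fx, fy, fz = _f(X / Xn), _f(Y / Yn), _f(Z / Zn)
    return LabColor(
        L_star=float(116.0 * fy - 16.0),
        a_star=float(500.0 * (fx - fy)),
        b_star=float(200.0 * (fy - fz)),
    )


def delta_series(
    measurements: Sequence[ReflectanceMeasurement],
    illuminant: str = "D65",
    observer: str = "10deg",
) -> list[ColorDelta]:
    """Per-timepoint Lab(t) - Lab(0) for one site's time-ordered series.

    The first measurement must be the pre-irradiation baseline (time_h = 0);
    all measurements must carry the same site label.
    """
    if not measurements:
        raise DomainError("empty measurement series")
    baseline = measurements[0]
    if baseline.time_h != 0:
        raise DomainError("first measurement must be the t=0 baseline")
    sites = {m.site for m in measurements}
    if len(sites) > 1:
        raise DomainError(f"series mixes sites {sorted(sites)}; pair by site label")
    times = [m.time_h for m in measurements]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise DomainError("measurements must be time-ordered")
    lab0 = reflectance_to_lab(baseline, illuminant, observer)
    out = []
    for m in measurements:
        if m is baseline:
            out.append(ColorDelta(0.0, 0.0, 0.0, 0.0))
            continue
        lab = reflectance_to_lab(m, illuminant, observer)
        out.append(
            ColorDelta(
                m.time_h,
                lab.L_star - lab0.L_star,
                lab.a_star - lab0.a_star,
                lab.b_star - lab0.b_star,
            )
        )
    return out


@dataclass(frozen=True)
class ResponseThresholds:
    """Classification thresholds: a response requires the delta to exceed the
    threshold at ``min_consecutive`` consecutive time points."""

    delta_a: float = 1.0
    delta_b: float = 1.0
    min_consecutive: int = 2


def _sustained(values: np.ndarray, threshold: float, run: int) -> bool:
    above = values > threshold
    count = 0
    for flag in above:
        count = count + 1 if flag else 0
        if count >= run:
            return True
    return False


def classify_response(
    deltas: Sequence[ColorDelta],
    thresholds: ResponseThresholds = ResponseThresholds(),
) -> dict[str, bool]:
    """Classify a delta series as erythema (sustained delta-a increase) and/or
    yellowing (sustained delta-b increase)."""
    if len(deltas) < 2:
        raise DomainError("classification needs at least 2 time points")
    da = np.array([d.delta_a for d in deltas])
    db = np.array([d.delta_b for d in deltas])
    return {
        "erythema": _sustained(da, thresholds.delta_a, thresholds.min_consecutive),
        "yellowing": _sustained(db, thresholds.delta_b, thresholds.min_consecutive),
    }
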