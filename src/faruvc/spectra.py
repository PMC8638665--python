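"""Spectral distributions and filter curves.

The substrate of the pipeline: wavelength-resolved lamp emission or surface
irradiance on a strictly ascending nanometre grid, either peak-relative
(``unit_kind="relative"``) or absolute (mW cm^-2 nm^-1,
``unit_kind="absolute"``).  All integrals are trapezoidal on the native grid;
the only resampling ever performed is linear interpolation of a filter's
transmission onto the spectrum grid.  Wavelengths are in-air nanometres.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

from .exceptions import DomainError, SpectrumFormatError

__all__ = [
    "SpectralDistribution",
    "FilterCurve",
    "read_spectrum",
    "write_spectrum",
    "normalize_to_peak",
    "apply_filter",
    "band_irradiance",
    "rescale_to_band_irradiance",
]

log = logging.getLogger(__name__)

_UNIT_KINDS = ("relative", "absolute")


def _validate_grid(wavelengths: np.ndarray) -> None:
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise SpectrumFormatError("spectral grid needs at least 2 points")
    if not np.all(np.diff(wavelengths) > 0):
        raise SpectrumFormatError("wavelength grid must be strictly ascending")


@dataclass(frozen=True)
class SpectralDistribution:
    """A spectrum on a strictly ascending wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly ascending wavelengths in nm (typically spanning 200-400 nm).
    values : array-like
        Non-negative spectral magnitude per nm; relative units or
        mW cm^-2 nm^-1 depending on ``unit_kind``.
    unit_kind : {"relative", "absolute"}
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit_kind: str = "relative"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        _validate_grid(w)
        if v.shape != w.shape:
            raise SpectrumFormatError("values and wavelengths differ in length")
        if np.any(v < 0):
            raise DomainError("spectral values must be non-negative")
        if self.unit_kind not in _UNIT_KINDS:
            raise DomainError(f"unit_kind must be one of {_UNIT_KINDS}")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FilterCurve:
    """Transmission-vs-wavelength curve of an optical filter; T in [0, 1]."""

    wavelengths_nm: np.ndarray
    transmission: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        t = np.asarray(self.transmission, dtype=float)
        _validate_grid(w)
        if t.shape != w.shape:
            raise SpectrumFormatError("transmission and wavelengths differ in length")
        if np.any((t < 0) | (t > 1)):
            raise DomainError("filter transmission must lie in [0, 1]")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "transmission", t)


_SPLIT = re.compile(r"[,\s]+")


def _parse_rows(stream: IO[str]) -> np.ndarray:
    rows = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = _SPLIT.split(line)
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"line {lineno}: expected two columns, got {len(parts)}"
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumFormatError(f"line {lineno}: non-numeric entry") from exc
    if len(rows) < 2:
        raise SpectrumFormatError("spectral file needs at least 2 data rows")
    return np.asarray(rows, dtype=float)


def read_spectrum(
    source: Union[str, Path, IO[str]], unit_kind: str = "relative"
) -> SpectralDistribution:
    """Read a two-column (wavelength nm, value) text spectrum.

    Whitespace- or comma-delimited; ``#`` starts a comment.  The wavelength
    column must already be strictly ascending — an unsorted file is rejected
    rather than silently sorted, since row order is part of the measurement
    record.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = _parse_rows(fh)
    else:
        data = _parse_rows(source)
    return SpectralDistribution(data[:, 0], data[:, 1], unit_kind)


def read_filter(source: Union[str, Path, IO[str]]) -> FilterCurve:
    """Read a two-column (wavelength nm, transmission) filter curve."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = _parse_rows(fh)
    else:
        data = _parse_rows(source)
    return FilterCurve(data[:, 0], data[:, 1])


def write_spectrum(
    s: SpectralDistribution, dest: Union[str, Path, IO[str]], header: str = ""
) -> None:
    """Write a spectrum as two-column text (nm, value), ``#`` comments."""
    buf = io.StringIO()
    if header:
        for line in header.splitlines():
            buf.write(f"# {line}\n")
    buf.write(f"# unit_kind: {s.unit_kind}\n")
    for w, v in zip(s.wavelengths_nm, s.values):
        buf.write(f"{w:.6g} {v:.9g}\n")
    text = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


def normalize_to_peak(s: SpectralDistribution) -> SpectralDistribution:
    """Scale so the peak value is exactly 1; the result is unit-relative."""
    peak = float(np.max(s.values))
    if peak <= 0:
        raise DomainError("cannot peak-normalize an all-zero spectrum")
    return SpectralDistribution(s.wavelengths_nm, s.values / peak, "relative")


def apply_filter(s: SpectralDistribution, f: FilterCurve) -> SpectralDistribution:
    """Multiply a spectrum by a filter's transmission.

    Transmission is linearly interpolated onto the spectrum grid.  Outside the
    filter's own grid the nearest endpoint value is held (physical filters
    plateau); a warning is logged when that extrapolation is exercised.
    """
    w = s.wavelengths_nm
    if w[0] < f.wavelengths_nm[0] or w[-1] > f.wavelengths_nm[-1]:
        log.warning(
            "filter grid [%g, %g] nm does not span spectrum [%g, %g] nm; "
            "holding endpoint transmission outside it",
            f.wavelengths_nm[0], f.wavelengths_nm[-1], w[0], w[-1],
        )
    t = np.interp(w, f.wavelengths_nm, f.transmission)
    return SpectralDistribution(w, s.values * t, s.unit_kind)


def band_irradiance(s: SpectralDistribution, lo_nm: float, hi_nm: float) -> float:
    """Trapezoidal integral of the spectrum over [lo_nm, hi_nm].

    Band edges falling between grid points are handled by linear
    interpolation (partial bins).  Units are value-units x nm, i.e.
    mW cm^-2 for an absolute spectrum.
    """
    w, v = s.wavelengths_nm, s.values
    if lo_nm > hi_nm:
        raise DomainError("band lower edge exceeds upper edge")
    if lo_nm < w[0] or hi_nm > w[-1]:
        raise DomainError(
            f"band [{lo_nm}, {hi_nm}] nm outside spectral grid [{w[0]}, {w[-1]}] nm"
        )
    if lo_nm == hi_nm:
        return 0.0
    inside = (w > lo_nm) & (w < hi_nm)
    grid = np.concatenate(([lo_nm], w[inside], [hi_nm]))
    vals = np.interp(grid, w, v)
    return float(np.trapezoid(vals, grid))


def rescale_to_band_irradiance(
    s: SpectralDistribution, target: float, lo_nm: float, hi_nm: float
) -> SpectralDistribution:
    """Scale a spectrum so its band integral equals ``target`` (mW cm^-2).

    The result is in absolute units.  This is how a relative lamp spectrum is
    pinned to a measured broadband irradiance (e.g. 6.1 mW cm^-2 over
    200-400 nm at the skin surface).
    """
    if target < 0:
        raise DomainError("target irradiance must be non-negative")
    current = band_irradiance(s, lo_nm, hi_nm)
    if current <= 0:
        raise DomainError("band integral is zero; cannot rescale")
    return SpectralDistribution(
        s.wavelengths_nm, s.values * (target / current), "absolute"
    )
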