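"""Monte Carlo radiative transfer in plane-parallel layered skin.

Photon packets are launched normally onto a laterally infinite stack of
tissue layers (a 5 x 5 cm exposure field is far wider than any UV
penetration depth, so tallies depend on depth z only; z is in micrometres,
zero at the surface, increasing into tissue).  Transport follows the
standard weighted-packet scheme: exponential free paths in the combined
attenuation mu_t = mu_a + mu_s, implicit capture (a fraction mu_a/mu_t of
the packet weight deposited at each interaction), Henyey-Greenstein
scattering, Fresnel reflection at the air-tissue surface (internal
boundaries are index-matched at n = 1.38), and Russian roulette below
weight 1e-4 with survival probability 0.1.

Fluence rate versus depth is estimated with the track-length estimator:
every path segment adds weight x path length to the depth bins it crosses,
normalised per unit incident irradiance, so an unattenuated collimated beam
scores exactly 1 in every bin.  Wavelengths are transported independently
(no fluorescence); the source spectrum enters only as per-wavelength
weights when profiles are integrated over a band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .exceptions import DomainError
from .spectra import SpectralDistribution, band_irradiance

__all__ = [
    "SkinLayer",
    "SkinModel",
    "PhotonState",
    "FluenceProfile",
    "sample_free_path",
    "sample_scatter",
    "fresnel_reflectance",
    "propagate_photon",
    "simulate_fluence",
    "fluence_at_depth",
    "fluence_ratio",
]

WEIGHT_ROULETTE = 1e-4
ROULETTE_SURVIVAL = 0.1


# ---------------------------------------------------------------------------
# model containers

@dataclass(frozen=True)
class SkinLayer:
    """One optical layer: thickness and wavelength-resolved coefficients.

    ``mu_a_mm`` / ``mu_s_mm`` are absorption / scattering coefficients in
    mm^-1 on ``wavelengths_nm``; ``g`` is the Henyey-Greenstein anisotropy.
    """

    name: str
    thickness_um: float
    wavelengths_nm: np.ndarray
    mu_a_mm: np.ndarray
    mu_s_mm: np.ndarray
    g: float

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        a = np.asarray(self.mu_a_mm, dtype=float)
        s = np.asarray(self.mu_s_mm, dtype=float)
        if self.thickness_um <= 0:
            raise DomainError(f"layer {self.name!r}: thickness must be positive")
        if a.shape != w.shape or s.shape != w.shape:
            raise DomainError(f"layer {self.name!r}: coefficient grids mismatch")
        if np.any(a < 0) or np.any(s < 0):
            raise DomainError(f"layer {self.name!r}: coefficients must be >= 0")
        if np.any((a == 0) & (s == 0)):
            raise DomainError(
                f"layer {self.name!r}: mu_a and mu_s both zero at some wavelength"
            )
        if not -1 < self.g < 1:
            raise DomainError(f"layer {self.name!r}: g must lie in (-1, 1)")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "mu_a_mm", a)
        object.__setattr__(self, "mu_s_mm", s)

    def mu_a_at(self, wavelength_nm: float) -> float:
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.mu_a_mm))

    def mu_s_at(self, wavelength_nm: float) -> float:
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.mu_s_mm))


def _layer_from_params(p: dict, grid: np.ndarray) -> SkinLayer:
    lam = grid
    mu_a = (
        p["mua_a1"] * np.exp(-(lam - 222.0) / p["mua_tau1"])
        + p["mua_a2"] * np.exp(-(lam - 222.0) / p["mua_tau2"])
        + p["mua_melanin"] * (lam / 400.0) ** -3
    )
    mu_s = p["mus_400"] * (lam / 400.0) ** -p["mus_power"]
    return SkinLayer(p["name"], p["thickness_um"], lam, mu_a, mu_s, p["g"])


@dataclass(frozen=True)
class SkinModel:
    """Ordered layer stack (surface -> depth) with named epidermal depth markers."""

    layers: tuple[SkinLayer, ...]
    markers: dict[str, float]
    ambient_n: float = 1.0
    tissue_n: float = 1.38
    name: str = "custom"
    params: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise DomainError("model needs at least one layer")
        depths = sorted(self.markers.values())
        if depths != list(self.markers.values()):
            pass  # dict order is presentation only; validated against span below
        total = self.total_thickness_um
        for k, v in self.markers.items():
            if not 0 <= v <= total:
                raise DomainError(f"marker {k!r} at {v} um outside model span")

    @property
    def total_thickness_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    @property
    def boundaries_um(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum([l.thickness_um for l in self.layers])))

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.layers[0].wavelengths_nm

    @classmethod
    def homogeneous(
        cls,
        mu_a_mm: float,
        mu_s_mm: float,
        g: float = 0.0,
        thickness_um: float = 2000.0,
        wavelengths_nm: Sequence[float] = (200.0, 400.0),
        ambient_n: float = 1.0,
        tissue_n: float = 1.0,
    ) -> "SkinModel":
        """Single uniform slab with constant coefficients — the analytic
        test-bench geometry (Beer-Lambert when mu_s = 0 and indices match)."""
        grid = np.asarray(wavelengths_nm, dtype=float)
        layer = SkinLayer(
            "slab", thickness_um, grid,
            np.full_like(grid, float(mu_a_mm)),
            np.full_like(grid, float(mu_s_mm)),
            g,
        )
        return cls((layer,), {}, ambient_n, tissue_n, name="homogeneous")

    @classmethod
    def from_toml(cls, source: str | Path) -> "SkinModel":
        import tomllib

        text = Path(source).read_text(encoding="utf-8")
        cfg = tomllib.loads(text)
        m = cfg["model"]
        grid = np.arange(
            m["grid_lo_nm"], m["grid_hi_nm"] + 0.5 * m["grid_step_nm"], m["grid_step_nm"]
        )
        layers = tuple(_layer_from_params(p, grid) for p in cfg["layer"])
        model = cls(
            layers,
            dict(cfg["markers"]),
            ambient_n=m["ambient_n"],
            tissue_n=m["tissue_n"],
            name=m["name"],
            params=cfg,
        )
        # basal layer must sit at the bottom of the deepest epidermal layer
        if "basal_layer" in model.markers:
            epi_bottom = model.boundaries_um[
                min(2, len(model.layers))
            ]  # SC + living epidermis
            if not math.isclose(model.markers["basal_layer"], epi_bottom):
                raise DomainError(
                    "basal_layer marker must coincide with the epidermal base"
                )
        return model

    def to_toml(self, dest: str | Path) -> None:
        """Serialise the parametric preset back to TOML (round-trips exactly)."""
        if self.params is None:
            raise DomainError("model was not built from a parametric preset")
        lines = []
        m = self.params["model"]
        lines.append("[model]")
        for k, v in m.items():
            lines.append(f"{k} = {v!r}" if isinstance(v, str) else f"{k} = {float(v)!r}")
        lines.append("")
        lines.append("[markers]")
        for k, v in self.params["markers"].items():
            lines.append(f"{k} = {float(v)!r}")
        for p in self.params["layer"]:
            lines.append("")
            lines.append("[[layer]]")
            for k, v in p.items():
                lines.append(
                    f"{k} = {v!r}" if isinstance(v, str) else f"{k} = {float(v)!r}"
                )
        Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def coefficients_at(self, wavelength_nm: float):
        """Per-layer (mu_a, mu_s, g) arrays in um^-1 at one wavelength."""
        mu_a = np.array([l.mu_a_at(wavelength_nm) * 1e-3 for l in self.layers])
        mu_s = np.array([l.mu_s_at(wavelength_nm) * 1e-3 for l in self.layers])
        g = np.array([l.g for l in self.layers])
        return mu_a, mu_s, g


@dataclass
class PhotonState:
    """A Monte Carlo photon packet."""

    position_um: np.ndarray  # (x, y, z), z >= 0 downward
    direction: np.ndarray  # unit vector
    weight: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise DomainError("direction must be a unit vector")
        if not 0 < self.weight <= 1:
            raise DomainError("weight must lie in (0, 1]")


# ---------------------------------------------------------------------------
# elementary sampling operations

def sample_free_path(mu_t_mm: float, u: float) -> float:
    """Exponential free path -ln(u)/mu_t in mm; mu_t = 0 gives +inf."""
    if mu_t_mm < 0:
        raise DomainError("mu_t must be non-negative")
    if not 0 < u < 1:
        raise DomainError("u must lie in (0, 1)")
    if mu_t_mm == 0:
        return math.inf
    return -math.log(u) / mu_t_mm


def _hg_cos(g: float, u: float) -> float:
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def _rotate(ux: float, uy: float, uz: float, cos_t: float, phi: float):
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p, sin_p = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t * (1.0 if uz > 0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nz = -sin_t * cos_p * den + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


def sample_scatter(direction: Sequence[float], g: float, u1: float, u2: float) -> np.ndarray:
    """Henyey-Greenstein scatter: deflect ``direction`` by (theta, phi).

    cos(theta) is drawn from the HG inverse CDF using ``u1`` (isotropic,
    2*u1 - 1, when g = 0); phi = 2*pi*u2.  Returns a renormalised unit vector.
    """
    if not -1 < g < 1:
        raise DomainError("g must lie in (-1, 1)")
    cos_t = _hg_cos(g, u1)
    phi = 2.0 * math.pi * u2
    ux, uy, uz = (float(c) for c in direction)
    return np.array(_rotate(ux, uy, uz, cos_t, phi))


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarised Fresnel reflection probability at a planar boundary.

    ``cos_incident`` is the cosine of the angle of incidence in medium n1.
    Beyond the critical angle (n1 > n2) the result is 1 (total internal
    reflection).
    """
    if n1 <= 0 or n2 <= 0:
        raise DomainError("refractive indices must be positive")
    if not 0 < cos_incident <= 1:
        raise DomainError("cos_incident must lie in (0, 1]")
    if n1 == n2:
        return 0.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_incident * cos_incident))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_incident - n2 * cos_t) / (n1 * cos_incident + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_incident) / (n1 * cos_t + n2 * cos_incident)
    return 0.5 * (rs * rs + rp * rp)


# ---------------------------------------------------------------------------
# single-photon reference walk (pure Python, event-recording)

def propagate_photon(
    state: PhotonState, model: SkinModel, rng: np.random.Generator
) -> dict:
    """Walk one photon packet to termination, recording every deposition.

    Returns a ledger dict with ``events`` (list of (z_um, weight_deposited)),
    ``fate`` ("absorbed" | "reflected" | "transmitted" | "roulette"), the
    escaped/deposited weights and the roulette adjustment; per photon,
    launched = deposited + escaped + roulette_net to float precision.

    This is the readable single-packet reference; bulk simulation goes
    through the compiled kernel in :func:`simulate_fluence`, which implements
    the same walk.
    """
    bounds = model.boundaries_um
    mu_a, mu_s, g = model.coefficients_at(state.wavelength_nm)
    n1, n2 = model.ambient_n, model.tissue_n
    x, y, z = state.position_um
    ux, uy, uz = state.direction
    w = state.weight
    launched = w
    events: list[tuple[float, float]] = []
    deposited = 0.0
    escaped = 0.0
    roulette_net = 0.0
    fate = "absorbed"
    layer = 0
    nlayer = len(model.layers)
    alive = True
    while alive:
        if not (math.isfinite(z) and math.isfinite(uz)):
            raise RuntimeError("non-finite photon state (internal error)")
        mt = mu_a[layer] + mu_s[layer]
        s_opt = -math.log(rng.random())  # dimensionless optical path
        while s_opt > 0 and alive:
            if uz > 0:
                d_bound = (bounds[layer + 1] - z) / uz
            elif uz < 0:
                d_bound = (bounds[layer] - z) / uz
            else:
                d_bound = math.inf
            step = s_opt / mt if mt > 0 else math.inf
            if d_bound < step:
                x += ux * d_bound
                y += uy * d_bound
                z = bounds[layer + 1] if uz > 0 else bounds[layer]
                s_opt -= d_bound * mt
                if uz < 0 and layer == 0:
                    r = fresnel_reflectance(n2, n1, -uz)
                    if rng.random() < r:
                        uz = -uz
                    else:
                        escaped += w
                        fate = "reflected"
                        alive = False
                elif uz > 0 and layer == nlayer - 1:
                    escaped += w
                    fate = "transmitted"
                    alive = False
                else:
                    layer += 1 if uz > 0 else -1
            else:
                x += ux * step
                y += uy * step
                z += uz * step
                s_opt = 0.0
                dep = w * mu_a[layer] / mt
                deposited += dep
                events.append((z, dep))
                w -= dep
                if w < WEIGHT_ROULETTE:
                    if w <= 0:
                        alive = False
                    elif rng.random() < ROULETTE_SURVIVAL:
                        roulette_net -= w * (1.0 / ROULETTE_SURVIVAL - 1.0)
                        w /= ROULETTE_SURVIVAL
                    else:
                        roulette_net += w
                        fate = "roulette"
                        alive = False
                if alive:
                    ux, uy, uz = _rotate(
                        ux, uy, uz, _hg_cos(g[layer], rng.random()),
                        2.0 * math.pi * rng.random(),
                    )
    return {
        "events": events,
        "fate": fate,
        "launched": launched,
        "deposited": deposited,
        "escaped": escaped,
        "roulette_net": roulette_net,
        "final_position": np.array([x, y, z]),
    }


# ---------------------------------------------------------------------------
# compiled bulk kernel

@njit(cache=True)
def _transport_kernel(
    n_photons, seed, mu_a, mu_s, g, bounds, n_ambient, n_tissue,
    bin_width, n_bins, w_roulette, p_survival,
):  # pragma: no cover - exercised via simulate_fluence
    np.random.seed(seed)
    fl = np.zeros(n_bins)
    fl2 = np.zeros(n_bins)
    absorbed_bins = np.zeros(n_bins)
    refl = 0.0
    trans = 0.0
    absorbed = 0.0
    roulette_net = 0.0
    nlayer = mu_a.shape[0]
    z_max = bounds[nlayer]
    # specular reflection at normal incidence on entry
    r_sp = ((n_ambient - n_tissue) / (n_ambient + n_tissue)) ** 2
    path = np.zeros(n_bins)
    for _ in range(n_photons):
        for i in range(n_bins):
            path[i] = 0.0
        refl += r_sp
        w = 1.0 - r_sp
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        alive = True
        while alive:
            mt = mu_a[layer] + mu_s[layer]
            s_opt = -math.log(np.random.random())
            while s_opt > 0.0 and alive:
                if uz > 0.0:
                    d_bound = (bounds[layer + 1] - z) / uz
                elif uz < 0.0:
                    d_bound = (bounds[layer] - z) / uz
                else:
                    d_bound = 1e30
                if mt > 0.0:
                    step = s_opt / mt
                else:
                    step = 1e30
                if d_bound < step:
                    move = d_bound
                else:
                    move = step
                # track-length tally over [z, z + move*uz]
                z_new = z + move * uz
                auz = abs(uz)
                if auz < 1e-12:
                    ib = int(z / bin_width)
                    if 0 <= ib < n_bins:
                        path[ib] += w * move
                else:
                    zlo = z if z < z_new else z_new
                    zhi = z_new if z_new > z else z
                    if zlo < 0.0:
                        zlo = 0.0
                    if zhi > z_max:
                        zhi = z_max
                    i0 = int(zlo / bin_width)
                    i1 = int(zhi / bin_width)
                    if i0 < 0:
                        i0 = 0
                    if i1 > n_bins - 1:
                        i1 = n_bins - 1
                    for ib in range(i0, i1 + 1):
                        lo = ib * bin_width
                        hi = lo + bin_width
                        if zlo > lo:
                            lo = zlo
                        if zhi < hi:
                            hi = zhi
                        if hi > lo:
                            path[ib] += w * (hi - lo) / auz
                if d_bound < step:
                    z = bounds[layer + 1] if uz > 0.0 else bounds[layer]
                    s_opt -= d_bound * mt
                    if uz < 0.0 and layer == 0:
                        # air-tissue surface: Fresnel from inside
                        ci = -uz
                        sin_t = n_tissue / n_ambient * math.sqrt(1.0 - ci * ci)
                        if sin_t >= 1.0:
                            r = 1.0
                        else:
                            ct = math.sqrt(1.0 - sin_t * sin_t)
                            rs = (n_tissue * ci - n_ambient * ct) / (
                                n_tissue * ci + n_ambient * ct
                            )
                            rp = (n_tissue * ct - n_ambient * ci) / (
                                n_tissue * ct + n_ambient * ci
                            )
                            r = 0.5 * (rs * rs + rp * rp)
                        if np.random.random() < r:
                            uz = -uz
                        else:
                            refl += w
                            alive = False
                    elif uz > 0.0 and layer == nlayer - 1:
                        trans += w
                        alive = False
                    else:
                        if uz > 0.0:
                            layer += 1
                        else:
                            layer -= 1
                else:
                    z = z_new
                    s_opt = 0.0
                    dep = w * mu_a[layer] / mt
                    absorbed += dep
                    ib = int(z / bin_width)
                    if ib > n_bins - 1:
                        ib = n_bins - 1
                    absorbed_bins[ib] += dep
                    w -= dep
                    if w < w_roulette:
                        if w <= 0.0:
                            alive = False
                        elif np.random.random() < p_survival:
                            roulette_net -= w * (1.0 / p_survival - 1.0)
                            w /= p_survival
                        else:
                            roulette_net += w
                            alive = False
                    if alive:
                        gg = g[layer]
                        u1 = np.random.random()
                        if gg == 0.0:
                            cos_t = 2.0 * u1 - 1.0
                        else:
                            tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u1)
                            cos_t = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                        phi = 2.0 * math.pi * np.random.random()
                        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                        cos_p = math.cos(phi)
                        sin_p = math.sin(phi)
                        if abs(uz) > 0.99999:
                            nx = sin_t * cos_p
                            ny = sin_t * sin_p
                            nz = cos_t if uz > 0.0 else -cos_t
                        else:
                            den = math.sqrt(1.0 - uz * uz)
                            nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
                            ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
                            nz = -sin_t * cos_p * den + uz * cos_t
                        norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                        ux = nx / norm
                        uy = ny / norm
                        uz = nz / norm
        for i in range(n_bins):
            fl[i] += path[i]
            fl2[i] += path[i] * path[i]
    return fl, fl2, absorbed_bins, refl, trans, absorbed, roulette_net


# ---------------------------------------------------------------------------
# wavelength-resolved simulation

@dataclass(frozen=True)
class FluenceProfile:
    """Depth- and wavelength-resolved fluence rate per unit incident irradiance.

    ``fluence[i, j]`` is the dimensionless fluence rate in depth bin i
    (half-open [edge_i, edge_{i+1}) um) at wavelength j; an unattenuated
    collimated beam gives 1.  ``source_values`` carries the source spectrum
    resampled onto the wavelength grid, used as weights when integrating
    over a band.  Tallies are weight fractions; the net Russian-roulette
    adjustment is folded into ``absorbed`` so that
    reflected + transmitted + absorbed = 1 per wavelength.
    """

    depth_edges_um: np.ndarray
    wavelengths_nm: np.ndarray
    fluence: np.ndarray  # (n_bins, n_wavelengths)
    fluence_sem: np.ndarray
    source_values: np.ndarray
    photons_per_wavelength: int
    seed: int
    reflected: np.ndarray
    transmitted: np.ndarray
    absorbed: np.ndarray

    @property
    def depth_centers_um(self) -> np.ndarray:
        return 0.5 * (self.depth_edges_um[:-1] + self.depth_edges_um[1:])


def simulate_fluence(
    model: SkinModel,
    source: SpectralDistribution,
    photons_per_wavelength: int = 10_000,
    depth_bin_um: float = 10.0,
    seed: int = 0,
    max_depth_um: float | None = None,
) -> FluenceProfile:
    """Run independent single-wavelength transport across the model's grid.

    The source spectrum is linearly resampled onto the model's wavelength
    grid (zero outside its support).  Each wavelength gets its own
    deterministic child seed, so a given (model, source, photons, seed)
    reproduces bit-identical output.  ``max_depth_um`` limits the tally span
    (default: full stack).
    """
    if photons_per_wavelength < 1:
        raise DomainError("photons_per_wavelength must be >= 1")
    grid = model.wavelengths_nm
    if source.wavelengths_nm[0] > grid[-1] or source.wavelengths_nm[-1] < grid[0]:
        raise DomainError("source spectrum does not overlap the model grid")
    src = np.interp(grid, source.wavelengths_nm, source.values, left=0.0, right=0.0)
    span = model.total_thickness_um if max_depth_um is None else float(max_depth_um)
    n_bins = max(1, int(round(span / depth_bin_um)))
    edges = np.arange(n_bins + 1) * depth_bin_um
    seeds = np.random.SeedSequence(seed).generate_state(grid.size) % (2**31)
    bounds = model.boundaries_um
    n = photons_per_wavelength
    fluence = np.empty((n_bins, grid.size))
    sem = np.empty((n_bins, grid.size))
    refl = np.empty(grid.size)
    trans = np.empty(grid.size)
    absorbed = np.empty(grid.size)
    for j, lam in enumerate(grid):
        mu_a, mu_s, g = model.coefficients_at(lam)
        fl, fl2, _, r, t, a, rn = _transport_kernel(
            n, int(seeds[j]), mu_a, mu_s, g, bounds,
            model.ambient_n, model.tissue_n,
            float(depth_bin_um), n_bins, WEIGHT_ROULETTE, ROULETTE_SURVIVAL,
        )
        # per-photon track length l has fluence estimate mean(l)/bin_width
        mean = fl / n
        var = np.maximum(fl2 / n - mean**2, 0.0) / max(n - 1, 1)
        fluence[:, j] = mean / depth_bin_um
        sem[:, j] = np.sqrt(var) / depth_bin_um
        refl[j] = r / n
        trans[j] = t / n
        absorbed[j] = (a + rn) / n
    return FluenceProfile(
        edges, grid.copy(), fluence, sem, src, n, seed, refl, trans, absorbed
    )


def _band_weighted(profile: FluenceProfile, row: np.ndarray, lo_nm: float, hi_nm: float) -> float:
    spec = SpectralDistribution(
        profile.wavelengths_nm, row * profile.source_values, "absolute"
    )
    return band_irradiance(spec, lo_nm, hi_nm)


def fluence_at_depth(
    profile: FluenceProfile, depth_um: float, band_nm: tuple[float, float]
) -> float:
    """Source-weighted band integral of fluence in the bin containing ``depth_um``.

    Returns the trapezoidal integral over [lo, hi] nm of
    fluence(depth, lambda) x source(lambda); with an absolute source this is
    a fluence-rate in mW cm^-2.  A zero-width band gives 0.
    """
    edges = profile.depth_edges_um
    if not edges[0] <= depth_um <= edges[-1]:
        raise DomainError(f"depth {depth_um} um outside profile span")
    i = min(int(np.searchsorted(edges, depth_um, side="right")) - 1, len(edges) - 2)
    i = max(i, 0)
    return _band_weighted(profile, profile.fluence[i, :], *band_nm)


def fluence_ratio(
    p_a: FluenceProfile,
    p_b: FluenceProfile,
    depth_um: float,
    band_nm: tuple[float, float],
) -> tuple[float, float]:
    """Fold difference of band-integrated fluence A/B at one depth.

    Returns (ratio, sigma) with sigma a first-order Monte Carlo uncertainty
    propagated from the per-bin standard errors.  A zero denominator yields
    (inf, inf) with a warning.
    """
    if p_a.depth_edges_um.shape != p_b.depth_edges_um.shape or not np.allclose(
        p_a.depth_edges_um, p_b.depth_edges_um
    ):
        raise DomainError("profiles have mismatched depth grids")
    if not np.array_equal(p_a.wavelengths_nm, p_b.wavelengths_nm):
        raise DomainError("profiles have mismatched wavelength grids")
    fa = fluence_at_depth(p_a, depth_um, band_nm)
    fb = fluence_at_depth(p_b, depth_um, band_nm)
    edges = p_a.depth_edges_um
    i = max(min(int(np.searchsorted(edges, depth_um, side="right")) - 1, len(edges) - 2), 0)

    def band_sigma(p: FluenceProfile) -> float:
        w = p.wavelengths_nm
        mask = (w >= band_nm[0]) & (w <= band_nm[1])
        if not np.any(mask):
            return 0.0
        dl = np.gradient(w)[mask]
        contrib = p.fluence_sem[i, mask] * p.source_values[mask] * dl
        return float(np.sqrt(np.sum(contrib**2)))

    if fb == 0:
        import warnings

        warnings.warn("zero denominator in fluence ratio; returning inf")
        return math.inf, math.inf
    ratio = fa / fb
    sa, sb = band_sigma(p_a), band_sigma(p_b)
    sigma = abs(ratio) * math.sqrt(
        (sa / fa) ** 2 + (sb / fb) ** 2 if fa != 0 else (sb / fb) ** 2
    )
    return ratio, sigma
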