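# Methods

This note documents the models, defaults and numerical choices behind
`faruvc`, a toolkit for quantifying the skin-safety and germicidal trade-off
of far-UVC (222 nm KrCl excimer) sources.

## Spectral handling

Spectra live on their native strictly ascending nm grid; all integrals are
trapezoidal on that grid, with linear interpolation only at band edges
(partial bins) and when resampling a filter's transmission onto a spectrum
grid. Outside a filter's own grid the endpoint transmission is held constant
(physical filters plateau) and a warning is logged. Wavelengths are in-air
nm; no vacuum correction. Unsorted spectral files are rejected rather than
sorted, because row order is part of the measurement record.

## Actinic-hazard dosimetry

Radiant exposure is the exact product irradiance (mW cm^-2) x time (s) in
mJ cm^-2; a separate display helper rounds to 2 significant figures, the
convention of published exposure tables (1525 prints as 1500, 18 300 as
18 000; an exact 6.1 x 1000 = 6100 therefore prints as 6100 even where a
nominal 6.0 mW cm^-2 plan would print 6000 — the report footnote records
this). The ICNIRP actinic table (200-400 nm, anchored at S = 1 and
3 mJ cm^-2 at 270 nm) is shipped as package data. Exposure *limits* are
interpolated linearly in wavelength — this yields 23 mJ cm^-2 at 222 nm
from the 220/225 nm entries — while S(lambda) is interpolated log-linearly,
the standard practice for a quantity spanning five decades. Germicidal
timing assumes first-order (single-exponential) inactivation: surviving
fraction 10^(-dose/D90). Packaged constants: HCoV-229E aerosol
k = 4.1 cm^2 mJ^-1 and HCoV-OC43 aerosol k = 5.9 cm^2 mJ^-1 (Buonanno et
al. 2020), and a SARS-CoV-2 surface D90 of 1.19 mJ cm^-2 derived from the
reported 99.7% reduction at 3.0 mJ cm^-2 (Kitagawa et al. 2021) under the
same single-exponential assumption. Shoulder or multi-hit inactivation
models, ocular limits and multi-day dose bookkeeping are out of scope.

## Monte Carlo radiative transfer

Geometry is a laterally infinite plane-parallel layer stack with a normally
incident collimated beam: a 5 x 5 cm field is orders of magnitude wider
than UV penetration depths, so a pencil beam with translational invariance
gives identical depth-resolved tallies. Transport is the standard
weighted-packet walk: exponential free paths in mu_t, implicit capture
(weight x mu_a/mu_t deposited per interaction), Henyey-Greenstein
scattering sampled by the closed-form inverse CDF, and Russian roulette
below weight 1e-4 with survival probability 0.1. Fresnel reflection
(unpolarised average; total internal reflection beyond the critical angle)
is applied at the air-tissue surface only — every tissue layer shares
n = 1.38, so internal boundaries are matched; internal index mismatches are
a second-order effect on fluence-versus-depth. Fluence is estimated with
the track-length estimator (weight x path length per depth bin per bin
width), normalised per unit incident irradiance, so an unattenuated beam
scores exactly 1. The per-wavelength conservation ledger
(reflected + transmitted + absorbed = launched) closes to better than 1e-6;
the net Russian-roulette weight adjustment — bounded by the 1e-4 threshold
and unbiased in expectation — is folded into the absorbed tally so the
three reported fractions sum to one exactly.

Wavelengths are transported independently on the model's 2 nm grid over
200-400 nm (no fluorescence or other wavelength coupling); the source
spectrum enters only as per-wavelength weights when a profile is integrated
over a band. Each wavelength draws a deterministic child seed from the run
seed, making output bit-identical for identical inputs. The bulk kernel is
a compiled (numba) loop; `propagate_photon` is a readable pure-Python
single-packet reference implementing the identical walk with an
event-by-event ledger.

`SkinModel.homogeneous` provides the analytic test bench: with mu_s = 0 and
matched indices the binned fluence must match the bin-averaged
Beer-Lambert profile within Monte Carlo error, which the suite checks at
every bin with 1e5 packets.

### Skin optics preset

The published descriptions of 5-layer UV skin models defer their optical
property tables to prior work, so the packaged preset is an explicit
stand-in with every constant in `presets/skin_default.toml`: stratum
corneum 20 um, living epidermis 80 um (markers: top of epidermis 20 um,
mid-epidermis 60 um, basal layer 100 um — coinciding with the epidermal
base), papillary dermis 150 um, reticular dermis 1000 um, and a subcutis
backstop. Per layer, mu_a(lambda) is a decreasing double exponential
referenced to 222 nm (fast protein/nucleic-acid term, tau ~15 nm, ~80-90
mm^-1 at 222 nm in the epidermis, falling to a few mm^-1 by 300 nm) plus a
melanin-like (lambda/400)^-3 term; mu_s(lambda) is a (lambda/400)^-1.5
power law (25-50 mm^-1 at 400 nm) with g = 0.9. These magnitudes give
222 nm a ~10 um attenuation length (strong superficial absorption, the
defining property of far-UVC in tissue) while 300+ nm reaches the basal
layer — so the filtered-vs-unfiltered basal-layer fold difference over
240-320 nm is checked as an order-of-magnitude property (expected within
[10, 1000]), not as an exact figure; the depth markers are configurable
because "top/middle of epidermis" have no unique published depths.

## Colorimetry

Reflectance spectra (visible range, 10 nm pitch) are converted to CIELAB
through tristimulus integration against shipped illuminant x observer
weight tables — D65 with the CIE 1964 10-degree observer by default
(typical of handheld sphere spectrophotometers; D65/E and 10-deg/2-deg are
switchable), specular component treated as included. The white point is
computed from the same tables, so a perfect diffuser maps to
(L* = 100, a* = 0, b* = 0) identically and all flat spectra are exactly
neutral under every shipped pair. Skin response is delta-a (redness) and
delta-b (yellowness) relative to the t = 0 pre-irradiation baseline of the
same site. Classification uses an explicit threshold: a response requires
the delta to exceed 1.0 CIELAB units at two or more consecutive time
points (the underlying study reports presence/absence only, so the
threshold is a documented config, not an inferred constant).

## Synthetic-data generator

The generator emulates the three study inputs for which no numeric tables
exist; passing tests therefore validate the pipeline's internal
consistency, not any specific instrument or subject.

* **Lamp.** Gaussian 222 nm principal line (FWHM 2 nm), weak Gaussian side
  emissions at 240/248/258/270 nm (relative amplitudes 3e-3 to 8e-3, FWHM
  8 nm) and a 1e-6 flat continuum, peak-normalised. "Filtered" multiplies
  230-280 nm content by 1e-2 and "additional" filtering by 1e-4. The model
  is deterministic (a lamp spectrum has no per-draw noise); it mimics the
  qualitative structure of KrCl sources, not any measured curve.
* **Yellowing.** Phenomenological, making no mechanistic claim (the
  observed coloring is explicitly not melanin photo-oxidation): a blue-band
  chromophore (Gaussian absorber at 440 nm, sigma 50 nm) acting on a smooth
  pale-skin baseline reflectance (0.30 at 400 nm rising to 0.60 at 700 nm),
  with amplitude A(dose) = A_max (1 - exp(-(dose - threshold)/D0)) above a
  threshold dose and exponential clearance exp(-t/tau_h). Defaults:
  A_max = 0.5, D0 = 6000 mJ cm^-2, tau_h = 6 h (chosen so a 6000 mJ cm^-2
  response falls below the instrument noise floor by 24 h), threshold
  3000 mJ cm^-2 — an explicit, arbitrary placement inside the observed
  (1500, 6000] bracket — tape-strip removal fraction 0.8 ("initially
  reduced" is qualitative, so the factor is free), and per-band Gaussian
  reflectance noise sd 0.002. An optional green-band absorber generates
  erythema-like delta-a series for classifier testing; none is produced by
  default because no erythema was observed at any dose.
* **Kinetics recovery.** Because the CIELAB transform is nonlinear,
  delta-b(t) is not exactly exponential even when the chromophore amplitude
  is; recovery therefore inverts the known band shape — the least-squares
  projection of -ln(R(t)/R0) onto the chromophore profile — which is exact
  in the noise-free case, then fits log-amplitude versus time (tau) and the
  saturating dose response (A_max, D0) with scipy. Noise-free recovery of
  tau to 1e-6 relative and D0 to 5% across four doses is part of the
  acceptance suite.

## Problem sizes and determinism

Default study-condition runs use 1e4 photon packets per wavelength on the
2 nm grid with 10 um depth bins (the scale at which the basal-layer fold
difference carries a ~1% relative Monte Carlo error); analytic-oracle
checks use 1e5 packets, and orchestration smoke tests use a few hundred.
One master seed drives everything: stages derive fixed child seeds, and
every written table carries the config hash and seed in `#` comments, so a
config plus seed determines every output value.

## Known limitations

The skin preset is a parametric stand-in, not a fitted property table;
absolute fluence-depth values should not be read as subject-specific.
Polarisation, fluorescence, time-resolved transport, sweat-duct
microanatomy and DNA-damage action-spectrum convolution are excluded. The
colorimetric chain has no instrument drift model, and the yellowing model's
dose threshold is only bracketed, not identified, by the available
observations.
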