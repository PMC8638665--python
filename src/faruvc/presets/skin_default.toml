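# Default 5-layer skin optics preset for UV (200-400 nm) radiative transfer.
#
# Per-layer absorption is a double exponential of wavelength (protein /
# nucleic-acid dominated below ~240 nm) plus a melanin-like power-law term;
# scattering is a power-law decay with a fixed Henyey-Greenstein anisotropy.
# All coefficients are in mm^-1 with wavelength in nm:
#
#   mu_a(l) = a1 * exp(-(l - 222)/tau1) + a2 * exp(-(l - 222)/tau2)
#             + melanin * (l/400)^-3
#   mu_s(l) = mus_400 * (l/400)^-mus_power
#
# This is an explicit, documented stand-in parameterisation for pale
# (Fitzpatrick II) skin; every constant lives in this one file.

[model]
name = "default-5layer"
ambient_n = 1.0
tissue_n = 1.38
grid_lo_nm = 200.0
grid_hi_nm = 400.0
grid_step_nm = 2.0

[markers]
top_of_epidermis = 20.0
mid_epidermis = 60.0
basal_layer = 100.0

[[layer]]
name = "stratum_corneum"
thickness_um = 20.0
mua_a1 = 80.0
mua_tau1 = 15.0
mua_a2 = 10.0
mua_tau2 = 80.0
mua_melanin = 0.3
mus_400 = 50.0
mus_power = 1.5
g = 0.9

[[layer]]
name = "living_epidermis"
thickness_um = 80.0
mua_a1 = 60.0
mua_tau1 = 15.0
mua_a2 = 8.0
mua_tau2 = 80.0
mua_melanin = 0.6
mus_400 = 40.0
mus_power = 1.5
g = 0.9

[[layer]]
name = "papillary_dermis"
thickness_um = 150.0
mua_a1 = 35.0
mua_tau1 = 15.0
mua_a2 = 5.0
mua_tau2 = 90.0
mua_melanin = 0.3
mus_400 = 30.0
mus_power = 1.5
g = 0.9

[[layer]]
name = "reticular_dermis"
thickness_um = 1000.0
mua_a1 = 35.0
mua_tau1 = 15.0
mua_a2 = 5.0
mua_tau2 = 90.0
mua_melanin = 0.2
mus_400 = 30.0
mus_power = 1.5
g = 0.9

[[layer]]
name = "subcutis"
thickness_um = 3000.0
mua_a1 = 10.0
mua_tau1 = 20.0
mua_a2 = 2.0
mua_tau2 = 120.0
mua_melanin = 0.1
mus_400 = 25.0
mus_power = 1.5
g = 0.9
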