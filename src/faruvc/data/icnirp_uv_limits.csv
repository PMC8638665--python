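# ICNIRP guidelines on limits of exposure to ultraviolet radiation (180-400 nm),
# Health Physics 87(2):171-186 (2004). Actinic UV hazard: relative spectral
# effectiveness S(lambda) and 8-hour exposure limit (mJ cm^-2), anchored at
# S = 1, 3 mJ cm^-2 at 270 nm. Treated as physical constants.
# wavelength_nm,limit_mJ_cm2,S
200,100.0,0.030
205,59.0,0.051
210,40.0,0.075
215,32.0,0.095
220,25.0,0.120
225,20.0,0.150
230,16.0,0.190
235,13.0,0.240
240,10.0,0.300
245,8.3,0.360
250,7.0,0.430
254,6.0,0.500
255,5.8,0.520
260,4.6,0.650
265,3.7,0.810
270,3.0,1.000
275,3.1,0.960
280,3.4,0.880
285,3.9,0.770
290,4.7,0.640
295,5.6,0.540
300,10.0,0.300
305,50.0,0.060
310,200.0,0.015
315,1000.0,0.0030
320,2900.0,0.0010
325,6000.0,0.00050
330,7300.0,0.00041
335,8800.0,0.00034
340,11000.0,0.00028
345,13000.0,0.00024
350,15000.0,0.00020
355,19000.0,0.00016
360,23000.0,0.00013
365,27000.0,0.00011
370,32000.0,0.000093
375,39000.0,0.000077
380,47000.0,0.000064
385,57000.0,0.000053
390,68000.0,0.000044
395,83000.0,0.000036
400,100000.0,0.000030
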