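# Relative spectral power distributions of shipped illuminants, 10 nm pitch.
# D65: CIE standard daylight illuminant (normalized to 100 at 560 nm).
# E: equal-energy illuminant.
# wavelength_nm,D65,E
400,82.7549,100.0
410,91.4860,100.0
420,93.4318,100.0
430,86.6823,100.0
440,104.8650,100.0
450,117.0080,100.0
460,117.8120,100.0
470,114.8610,100.0
480,115.9230,100.0
490,108.8110,100.0
500,109.3540,100.0
510,107.8020,100.0
520,104.7900,100.0
530,107.6890,100.0
540,104.4050,100.0
550,104.0460,100.0
560,100.0000,100.0
570,96.3342,100.0
580,95.7880,100.0
590,88.6856,100.0
600,90.0062,100.0
610,89.5991,100.0
620,87.6987,100.0
630,83.2886,100.0
640,83.6992,100.0
650,80.0268,100.0
660,80.2146,100.0
670,82.2778,100.0
680,78.2842,100.0
690,69.7213,100.0
700,71.6091,100.0
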