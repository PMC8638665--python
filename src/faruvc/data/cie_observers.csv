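# CIE colour-matching functions, 10 nm pitch, 400-700 nm.
# obs10: CIE 1964 10-degree standard observer (x10,y10,z10).
# obs2:  CIE 1931 2-degree standard observer (x2,y2,z2).
# Values from the CIE tables as reproduced in ASTM E308.
# wavelength_nm,x10,y10,z10,x2,y2,z2
400,0.019110,0.002000,0.086011,0.014310,0.000396,0.067850
410,0.084736,0.008756,0.389366,0.043510,0.001210,0.207400
420,0.204492,0.021391,0.972542,0.134380,0.004000,0.645600
430,0.314679,0.038676,1.553480,0.283900,0.011600,1.385600
440,0.383734,0.062077,1.967280,0.348280,0.023000,1.747060
450,0.370702,0.089456,1.994800,0.336200,0.038000,1.772110
460,0.302273,0.128201,1.745370,0.290800,0.060000,1.669200
470,0.195618,0.185190,1.317560,0.195360,0.090980,1.287640
480,0.080507,0.253589,0.772125,0.095640,0.139020,0.812950
490,0.016172,0.339133,0.415254,0.032010,0.208020,0.465180
500,0.003816,0.460777,0.218502,0.004900,0.323000,0.272000
510,0.037465,0.606741,0.112044,0.009300,0.503000,0.158200
520,0.117749,0.761757,0.060709,0.063270,0.710000,0.078250
530,0.236491,0.875211,0.030451,0.165500,0.862000,0.042160
540,0.376772,0.961988,0.013676,0.290400,0.954000,0.020300
550,0.529826,0.991761,0.003988,0.433450,0.994950,0.008750
560,0.705224,0.997340,0.000000,0.594500,0.995000,0.003900
570,0.878655,0.955552,0.000000,0.762100,0.952000,0.002100
580,1.014160,0.868934,0.000000,0.916300,0.870000,0.001650
590,1.118520,0.777405,0.000000,1.026300,0.757000,0.001100
600,1.123990,0.658341,0.000000,1.062200,0.631000,0.000800
610,1.030480,0.527963,0.000000,1.002600,0.503000,0.000340
620,0.856297,0.398057,0.000000,0.854450,0.381000,0.000190
630,0.647467,0.283493,0.000000,0.642400,0.265000,0.000050
640,0.431567,0.179828,0.000000,0.447900,0.175000,0.000020
650,0.268329,0.107633,0.000000,0.283500,0.107000,0.000000
660,0.152568,0.060281,0.000000,0.164900,0.061000,0.000000
670,0.081261,0.031800,0.000000,0.087400,0.032000,0.000000
680,0.040851,0.015905,0.000000,0.046770,0.017000,0.000000
690,0.019941,0.007749,0.000000,0.022700,0.008210,0.000000
700,0.009577,0.003718,0.000000,0.011359,0.004102,0.000000
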