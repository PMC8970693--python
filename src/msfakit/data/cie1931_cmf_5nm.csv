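# CIE 1931 2-degree standard observer color matching functions, 5 nm spacing.
# Synthetic table: evaluated from the multi-lobe Gaussian analytic fit of
# Wyman, Sloan & Shirley, JCGT 2(2), 2013, which approximates the tabulated
# CIE 1931 observer to within ~1% of peak; negative lobe values clipped at 0.
# columns: wavelength_nm, xbar, ybar, zbar
360,0.000001,0.000041,0.000484
365,0.000003,0.000065,0.000988
370,0.000015,0.000103,0.001944
375,0.000056,0.000161,0.003688
380,0.000199,0.000249,0.006746
385,0.000635,0.000380,0.011935
390,0.001841,0.000573,0.020565
395,0.004842,0.000856,0.035076
400,0.011547,0.001263,0.060795
405,0.024974,0.001843,0.109573
410,0.048992,0.002660,0.204114
415,0.087165,0.003795,0.376686
420,0.140648,0.005352,0.652200
425,0.205822,0.007464,1.015247
430,0.273148,0.010291,1.386237
435,0.328703,0.014028,1.644401
440,0.358596,0.018907,1.734199
445,0.358492,0.025195,1.776416
450,0.343717,0.033195,1.781581
455,0.317193,0.043244,1.746987
460,0.281047,0.055708,1.671543
465,0.238100,0.070987,1.518934
470,0.191544,0.089532,1.295168
475,0.144650,0.111909,1.044914
480,0.100554,0.138919,0.810275
485,0.062112,0.171799,0.615761
490,0.031763,0.212424,0.466377
495,0.011402,0.263344,0.355056
500,0.002253,0.327358,0.271444
505,0.004335,0.406398,0.207056
510,0.016544,0.499838,0.156479
515,0.038564,0.602932,0.116568
520,0.070043,0.706498,0.085354
525,0.110616,0.798692,0.061351
530,0.159914,0.868640,0.043266
535,0.217535,0.916754,0.029931
540,0.282972,0.953939,0.020311
545,0.355509,0.979878,0.013520
550,0.434110,0.994464,0.008827
555,0.517327,0.998039,0.005653
560,0.603241,0.991282,0.003551
565,0.689454,0.975095,0.002188
570,0.773160,0.950398,0.001323
575,0.851268,0.916086,0.000784
580,0.920596,0.872446,0.000456
585,0.978092,0.820868,0.000260
590,1.021075,0.762896,0.000146
595,1.047459,0.700180,0.000080
600,1.055926,0.634432,0.000043
605,1.041222,0.567363,0.000023
610,1.000346,0.500619,0.000012
615,0.936388,0.435710,0.000006
620,0.854009,0.373953,0.000003
625,0.758875,0.316419,0.000001
630,0.657021,0.263902,0.000001
635,0.554231,0.216913,0.000000
640,0.455516,0.175680,0.000000
645,0.364770,0.140187,0.000000
650,0.284601,0.110204,0.000000
655,0.216349,0.085341,0.000000
660,0.160242,0.065098,0.000000
665,0.115638,0.048912,0.000000
670,0.081307,0.036197,0.000000
675,0.055700,0.026383,0.000000
680,0.037178,0.018940,0.000000
685,0.024178,0.013392,0.000000
690,0.015320,0.009326,0.000000
695,0.009458,0.006396,0.000000
700,0.005689,0.004320,0.000000
705,0.003334,0.002874,0.000000
710,0.001904,0.001883,0.000000
715,0.001059,0.001215,0.000000
720,0.000574,0.000772,0.000000
725,0.000303,0.000483,0.000000
730,0.000156,0.000298,0.000000
735,0.000078,0.000181,0.000000
740,0.000038,0.000108,0.000000
745,0.000018,0.000064,0.000000
750,0.000008,0.000037,0.000000
755,0.000004,0.000021,0.000000
760,0.000002,0.000012,0.000000
765,0.000001,0.000007,0.000000
770,0.000000,0.000004,0.000000
775,0.000000,0.000002,0.000000
780,0.000000,0.000001,0.000000
785,0.000000,0.000001,0.000000
790,0.000000,0.000000,0.000000
795,0.000000,0.000000,0.000000
800,0.000000,0.000000,0.000000
805,0.000000,0.000000,0.000000
810,0.000000,0.000000,0.000000
815,0.000000,0.000000,0.000000
820,0.000000,0.000000,0.000000
825,0.000000,0.000000,0.000000
830,0.000000,0.000000,0.000000
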