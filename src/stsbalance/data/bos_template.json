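{
 "_comment": "Synthetic default functional-BOS template: built from a synthetic COP-excursion recording (generate_cop_excursion_trial, seed=20), normalized left-foot coordinates.",
 "vertices": [
  [
   -0.10642,
   -0.198116
  ],
  [
   -0.097687,
   -0.197726
  ],
  [
   -0.088952,
   -0.197194
  ],
  [
   0.07692,
   -0.186631
  ],
  [
   0.087022,
   -0.185968
  ],
  [
   0.09719,
   -0.185138
  ],
  [
   0.107337,
   -0.183981
  ],
  [
   0.117387,
   -0.182378
  ],
  [
   0.127291,
   -0.180282
  ],
  [
   0.137013,
   -0.177669
  ],
  [
   0.146534,
   -0.174554
  ],
  [
   0.15577,
   -0.170845
  ],
  [
   0.164728,
   -0.166604
  ],
  [
   0.173418,
   -0.161889
  ],
  [
   0.181883,
   -0.156797
  ],
  [
   0.190101,
   -0.151329
  ],
  [
   0.198115,
   -0.145567
  ],
  [
   0.206018,
   -0.139646
  ],
  [
   0.381553,
   -0.006892
  ],
  [
   0.390834,
   0.000211
  ],
  [
   0.39995,
   0.007587
  ],
  [
   0.408587,
   0.015385
  ],
  [
   0.416566,
   0.023667
  ],
  [
   0.423745,
   0.032458
  ],
  [
   0.430012,
   0.041762
  ],
  [
   0.435108,
   0.051636
  ],
  [
   0.439037,
   0.062014
  ],
  [
   0.441719,
   0.07286
  ],
  [
   0.443332,
   0.084045
  ],
  [
   0.443788,
   0.095542
  ],
  [
   0.443367,
   0.107203
  ],
  [
   0.442115,
   0.118972
  ],
  [
   0.440394,
   0.130707
  ],
  [
   0.394695,
   0.405878
  ],
  [
   0.393082,
   0.415436
  ],
  [
   0.391197,
   0.424945
  ],
  [
   0.38892,
   0.434368
  ],
  [
   0.38626,
   0.44369
  ],
  [
   0.382951,
   0.452821
  ],
  [
   0.378974,
   0.461723
  ],
  [
   0.374369,
   0.470378
  ],
  [
   0.36904,
   0.47872
  ],
  [
   0.36289,
   0.486677
  ],
  [
   0.356029,
   0.494246
  ],
  [
   0.348607,
   0.50145
  ],
  [
   0.34061,
   0.508252
  ],
  [
   0.332162,
   0.514673
  ],
  [
   0.323439,
   0.520768
  ],
  [
   0.31467,
   0.526635
  ],
  [
   0.118998,
   0.656972
  ],
  [
   0.1125,
   0.6613
  ],
  [
   0.105994,
   0.665598
  ],
  [
   0.099404,
   0.669757
  ],
  [
   0.092696,
   0.673718
  ],
  [
   0.085849,
   0.677437
  ],
  [
   0.078861,
   0.680889
  ],
  [
   0.071687,
   0.683973
  ],
  [
   0.064343,
   0.686684
  ],
  [
   0.056821,
   0.688974
  ],
  [
   0.049132,
   0.690818
  ],
  [
   0.04128,
   0.692181
  ],
  [
   0.03328,
   0.693045
  ],
  [
   0.025165,
   0.693428
  ],
  [
   0.016964,
   0.693342
  ],
  [
   0.008718,
   0.692841
  ],
  [
   0.00046,
   0.691962
  ],
  [
   -0.007774,
   0.690763
  ],
  [
   -0.015946,
   0.689321
  ],
  [
   -0.024012,
   0.687752
  ],
  [
   -0.273224,
   0.638556
  ],
  [
   -0.279469,
   0.637277
  ],
  [
   -0.28571,
   0.635895
  ],
  [
   -0.291936,
   0.634381
  ],
  [
   -0.298097,
   0.63263
  ],
  [
   -0.304228,
   0.630744
  ],
  [
   -0.310234,
   0.628529
  ],
  [
   -0.316187,
   0.62616
  ],
  [
   -0.321955,
   0.623401
  ],
  [
   -0.327592,
   0.620384
  ],
  [
   -0.333044,
   0.617042
  ],
  [
   -0.338284,
   0.613358
  ],
  [
   -0.343302,
   0.609347
  ],
  [
   -0.348077,
   0.605012
  ],
  [
   -0.352583,
   0.600341
  ],
  [
   -0.356838,
   0.595395
  ],
  [
   -0.360807,
   0.590151
  ],
  [
   -0.364537,
   0.5847
  ],
  [
   -0.367988,
   0.579012
  ],
  [
   -0.371228,
   0.573194
  ],
  [
   -0.374219,
   0.567214
  ],
  [
   -0.377038,
   0.561177
  ],
  [
   -0.379664,
   0.555067
  ],
  [
   -0.38217,
   0.548972
  ],
  [
   -0.474864,
   0.317025
  ],
  [
   -0.477093,
   0.311422
  ],
  [
   -0.479293,
   0.305748
  ],
  [
   -0.481431,
   0.3
  ],
  [
   -0.483436,
   0.29418
  ],
  [
   -0.485369,
   0.288289
  ],
  [
   -0.487088,
   0.282334
  ],
  [
   -0.488726,
   0.276314
  ],
  [
   -0.490082,
   0.270247
  ],
  [
   -0.491332,
   0.264125
  ],
  [
   -0.492275,
   0.257974
  ],
  [
   -0.49308,
   0.251783
  ],
  [
   -0.493576,
   0.245583
  ],
  [
   -0.493912,
   0.239359
  ],
  [
   -0.493961,
   0.233141
  ],
  [
   -0.493819,
   0.226919
  ],
  [
   -0.493467,
   0.220704
  ],
  [
   -0.492901,
   0.214505
  ],
  [
   -0.492191,
   0.20831
  ],
  [
   -0.491275,
   0.202141
  ],
  [
   -0.490267,
   0.19597
  ],
  [
   -0.489076,
   0.189828
  ],
  [
   -0.487838,
   0.183673
  ],
  [
   -0.486548,
   0.177507
  ],
  [
   -0.441871,
   -0.035759
  ],
  [
   -0.439825,
   -0.0454
  ],
  [
   -0.437507,
   -0.055042
  ],
  [
   -0.434848,
   -0.064589
  ],
  [
   -0.431618,
   -0.073719
  ],
  [
   -0.427971,
   -0.082594
  ],
  [
   -0.423753,
   -0.09096
  ],
  [
   -0.418897,
   -0.098656
  ],
  [
   -0.413629,
   -0.105954
  ],
  [
   -0.40769,
   -0.11239
  ],
  [
   -0.401328,
   -0.118281
  ],
  [
   -0.394564,
   -0.123597
  ],
  [
   -0.387343,
   -0.128179
  ],
  [
   -0.379914,
   -0.132406
  ],
  [
   -0.372141,
   -0.135977
  ],
  [
   -0.36425,
   -0.139277
  ],
  [
   -0.356158,
   -0.142107
  ],
  [
   -0.347992,
   -0.144696
  ],
  [
   -0.339754,
   -0.147032
  ],
  [
   -0.331534,
   -0.149312
  ],
  [
   -0.192677,
   -0.1878
  ],
  [
   -0.184267,
   -0.190041
  ],
  [
   -0.175789,
   -0.192078
  ],
  [
   -0.167245,
   -0.193834
  ],
  [
   -0.158646,
   -0.195326
  ],
  [
   -0.15,
   -0.196518
  ],
  [
   -0.141318,
   -0.197383
  ],
  [
   -0.13261,
   -0.197971
  ],
  [
   -0.123886,
   -0.198276
  ],
  [
   -0.115155,
   -0.198304
  ]
 ],
 "center": [
  -0.15,
  0.3
 ]
}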