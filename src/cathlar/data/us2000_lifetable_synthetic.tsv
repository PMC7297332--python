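# PROVENANCE: synthetic sex-specific period life table emulating US 2000
# demographics.  Constructed by monotone (PCHIP) interpolation of
# survivorship anchors chosen to reproduce published summary statistics of
# the US 2000 period life tables (life expectancy at birth ~74.3 y male /
# ~79.7 y female; survival to age 65 ~0.80 male / ~0.88 female).  A smoothed
# stand-in for the national table, not a copy of it.
# survival = S(a) = P(alive at exact age a | alive at birth).
sex	age	survival
M	0	1.0
M	1	0.9924
M	2	0.991766
M	3	0.991411
M	4	0.991201
M	5	0.991
M	6	0.990787
M	7	0.990615
M	8	0.990459
M	9	0.990295
M	10	0.9901
M	11	0.989883
M	12	0.989657
M	13	0.989398
M	14	0.989087
M	15	0.9887
M	16	0.988097
M	17	0.987222
M	18	0.986177
M	19	0.985069
M	20	0.984
M	21	0.982955
M	22	0.981862
M	23	0.980741
M	24	0.979614
M	25	0.9785
M	26	0.977415
M	27	0.976344
M	28	0.975266
M	29	0.974159
M	30	0.973
M	31	0.971797
M	32	0.970561
M	33	0.969277
M	34	0.967928
M	35	0.9665
M	36	0.964992
M	37	0.963403
M	38	0.961718
M	39	0.959922
M	40	0.958
M	41	0.955928
M	42	0.953694
M	43	0.951295
M	44	0.94873
M	45	0.946
M	46	0.943079
M	47	0.939933
M	48	0.936548
M	49	0.932908
M	50	0.929
M	51	0.924794
M	52	0.92024
M	53	0.915288
M	54	0.909891
M	55	0.904
M	56	0.897458
M	57	0.890157
M	58	0.882129
M	59	0.8734
M	60	0.864
M	61	0.853666
M	62	0.84219
M	63	0.82968
M	64	0.816247
M	65	0.802
M	66	0.786636
M	67	0.769889
M	68	0.751923
M	69	0.732905
M	70	0.713
M	71	0.691878
M	72	0.669266
M	73	0.645415
M	74	0.620576
M	75	0.595
M	76	0.568424
M	77	0.540585
M	78	0.511734
M	79	0.482122
M	80	0.452
M	81	0.420803
M	82	0.388322
M	83	0.35534
M	84	0.322638
M	85	0.291
M	86	0.259594
M	87	0.227875
M	88	0.19706
M	89	0.168364
M	90	0.143
M	91	0.119852
M	92	0.097665
M	93	0.077452
M	94	0.060227
M	95	0.047
M	96	0.036367
M	97	0.026648
M	98	0.018445
M	99	0.012362
M	100	0.009
F	0	1.0
F	1	0.9938
F	2	0.993301
F	3	0.993022
F	4	0.992857
F	5	0.9927
F	6	0.992532
F	7	0.992394
F	8	0.99227
F	9	0.992144
F	10	0.992
F	11	0.991845
F	12	0.991689
F	13	0.99152
F	14	0.991327
F	15	0.9911
F	16	0.990799
F	17	0.990414
F	18	0.98998
F	19	0.989531
F	20	0.9891
F	21	0.988691
F	22	0.988281
F	23	0.987865
F	24	0.98744
F	25	0.987
F	26	0.986553
F	27	0.986099
F	28	0.98563
F	29	0.985134
F	30	0.9846
F	31	0.984026
F	32	0.983414
F	33	0.982758
F	34	0.982055
F	35	0.9813
F	36	0.980484
F	37	0.9796
F	38	0.978644
F	39	0.977611
F	40	0.9765
F	41	0.975285
F	42	0.97395
F	43	0.972502
F	44	0.970949
F	45	0.9693
F	46	0.96754
F	47	0.965642
F	48	0.963594
F	49	0.961384
F	50	0.959
F	51	0.956407
F	52	0.95357
F	53	0.95048
F	54	0.947127
F	55	0.9435
F	56	0.93952
F	57	0.93512
F	58	0.93031
F	59	0.9251
F	60	0.9195
F	61	0.913401
F	62	0.906694
F	63	0.899387
F	64	0.891486
F	65	0.883
F	66	0.87378
F	67	0.863673
F	68	0.852674
F	69	0.840784
F	70	0.828
F	71	0.814061
F	72	0.798741
F	73	0.78209
F	74	0.76416
F	75	0.745
F	76	0.724156
F	77	0.701297
F	78	0.67666
F	79	0.650482
F	80	0.623
F	81	0.593494
F	82	0.56155
F	83	0.527858
F	84	0.493111
F	85	0.458
F	86	0.421649
F	87	0.383542
F	88	0.34491
F	89	0.306986
F	90	0.271
F	91	0.235669
F	92	0.200093
F	93	0.166083
F	94	0.135448
F	95	0.11
F	96	0.088423
F	97	0.068571
F	98	0.051007
F	99	0.036296
F	100	0.025
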