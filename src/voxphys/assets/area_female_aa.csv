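# Supraglottal area function (female aa), distance from glottis [cm], area [cm^2].
# Smooth parametric approximation of published MRI-based vowel tract shapes
# (not a digitization of any single published table); formants verified to
# lie in physiologic ranges for the vowel.
0.0000,0.5000
0.1568,0.5046
0.3137,0.5092
0.4705,0.5138
0.6274,0.5185
0.7842,0.5231
0.9411,0.5277
1.0979,0.5323
1.2547,0.5369
1.4116,0.5415
1.5684,0.5461
1.7253,0.5495
1.8821,0.5465
2.0389,0.5435
2.1958,0.5405
2.3526,0.5375
2.5095,0.5345
2.6663,0.5315
2.8232,0.5285
2.9800,0.5255
3.1368,0.5225
3.2937,0.5195
3.4505,0.5165
3.6074,0.5135
3.7642,0.5105
3.9211,0.5075
4.0779,0.5045
4.2347,0.5015
4.3916,0.4985
4.5484,0.4955
4.7053,0.4925
4.8621,0.4894
5.0189,0.4864
5.1758,0.4834
5.3326,0.4804
5.4895,0.4774
5.6463,0.4744
5.8032,0.4714
5.9600,0.4684
6.1168,0.4654
6.2737,0.4624
6.4305,0.4611
6.5874,0.4666
6.7442,0.4722
6.9011,0.4777
7.0579,0.4833
7.2147,0.4888
7.3716,0.4944
7.5284,0.4999
7.6853,2.3512
7.8421,3.6194
7.9989,3.6779
8.1558,3.7363
8.3126,3.7948
8.4695,3.8532
8.6263,3.9117
8.7832,3.9701
8.9400,4.0286
9.0968,4.0870
9.2537,4.1455
9.4105,4.1995
9.5674,4.1927
9.7242,4.1859
9.8811,4.1791
10.0379,4.1723
10.1947,4.1654
10.3516,4.1586
10.5084,4.1518
10.6653,4.1450
10.8221,4.1382
10.9789,4.1314
11.1358,4.1245
11.2926,4.1177
11.4495,4.1109
11.6063,4.1041
11.7632,4.0973
11.9200,4.0904
12.0768,4.0836
12.2337,4.0768
12.3905,4.0700
12.5474,4.0632
12.7042,4.0563
12.8611,4.0495
13.0179,4.0427
13.1747,4.0359
13.3316,4.0291
13.4884,4.0222
13.6453,4.0154
13.8021,4.0086
13.9589,4.0018
14.1158,3.9743
14.2726,3.9394
14.4295,3.9046
14.5863,3.8697
14.7432,3.8349
14.9000,3.8000
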