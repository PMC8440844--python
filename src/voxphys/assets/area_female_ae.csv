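# Supraglottal area function (female ae), distance from glottis [cm], area [cm^2].
# Smooth parametric approximation of published MRI-based vowel tract shapes
# (not a digitization of any single published table); formants verified to
# lie in physiologic ranges for the vowel.
0.0000,0.4000
0.1568,0.4121
0.3137,0.4241
0.4705,0.4362
0.6274,0.4483
0.7842,0.4603
0.9411,0.4724
1.0979,0.4845
1.2547,0.4965
1.4116,0.5687
1.5684,0.6652
1.7253,0.7617
1.8821,0.8582
2.0389,0.9547
2.1958,1.0513
2.3526,1.1478
2.5095,1.2443
2.6663,1.3133
2.8232,1.3446
2.9800,1.3760
3.1368,1.4074
3.2937,1.4387
3.4505,1.4701
3.6074,1.5015
3.7642,1.5328
3.9211,1.5642
4.0779,1.5956
4.2347,1.6269
4.3916,1.6583
4.5484,1.6897
4.7053,1.7211
4.8621,1.7524
5.0189,1.7838
5.1758,1.7913
5.3326,1.7732
5.4895,1.7551
5.6463,1.7370
5.8032,1.7189
5.9600,1.7008
6.1168,1.6827
6.2737,1.6646
6.4305,1.6465
6.5874,1.6284
6.7442,1.6103
6.9011,1.5922
7.0579,1.5741
7.2147,1.5560
7.3716,1.5379
7.5284,1.5198
7.6853,1.5017
7.8421,1.5398
7.9989,1.5837
8.1558,1.6276
8.3126,1.6715
8.4695,1.7155
8.6263,1.7594
8.7832,1.8033
8.9400,1.8472
9.0968,1.8911
9.2537,1.9350
9.4105,1.9789
9.5674,2.0229
9.7242,2.0668
9.8811,2.1107
10.0379,2.1546
10.1947,2.1985
10.3516,2.3102
10.5084,2.4243
10.6653,2.5384
10.8221,2.6524
10.9789,2.7665
11.1358,2.8806
11.2926,2.9946
11.4495,3.1087
11.6063,3.2228
11.7632,3.3368
11.9200,3.4509
12.0768,3.5650
12.2337,3.6790
12.3905,3.7931
12.5474,3.8693
12.7042,3.9432
12.8611,4.0170
13.0179,4.0908
13.1747,4.1646
13.3316,4.2384
13.4884,4.3122
13.6453,4.3860
13.8021,4.4598
13.9589,4.5336
14.1158,4.5921
14.2726,4.5137
14.4295,4.4353
14.5863,4.3568
14.7432,4.2784
14.9000,4.2000
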