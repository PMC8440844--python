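# Supraglottal area function (male aa), distance from glottis [cm], area [cm^2].
# Smooth parametric approximation of published MRI-based vowel tract shapes
# (not a digitization of any single published table); formants verified to
# lie in physiologic ranges for the vowel.
0.0000,0.6000
0.1842,0.6055
0.3684,0.6111
0.5526,0.6166
0.7368,0.6221
0.9211,0.6276
1.1053,0.6332
1.2895,0.6387
1.4737,0.6442
1.6579,0.6497
1.8421,0.6553
2.0263,0.6594
2.2105,0.6554
2.3947,0.6514
2.5789,0.6474
2.7632,0.6433
2.9474,0.6393
3.1316,0.6353
3.3158,0.6313
3.5000,0.6273
3.6842,0.6233
3.8684,0.6192
4.0526,0.6152
4.2368,0.6112
4.4211,0.6072
4.6053,0.6032
4.7895,0.5991
4.9737,0.5951
5.1579,0.5911
5.3421,0.5871
5.5263,0.5831
5.7105,0.5790
5.8947,0.5750
6.0789,0.5710
6.2632,0.5670
6.4474,0.5630
6.6316,0.5589
6.8158,0.5549
7.0000,0.5509
7.1842,0.5469
7.3684,0.5429
7.5526,0.5423
7.7368,0.5505
7.9211,0.5587
8.1053,0.5669
8.2895,0.5751
8.4737,0.5833
8.6579,0.5915
8.8421,0.5996
9.0263,2.7452
9.2105,4.2745
9.3947,4.3492
9.5789,4.4239
9.7632,4.4986
9.9474,4.5733
10.1316,4.6479
10.3158,4.7226
10.5000,4.7973
10.6842,4.8720
10.8684,4.9467
11.0526,4.9976
11.2368,4.9892
11.4211,4.9809
11.6053,4.9725
11.7895,4.9641
11.9737,4.9557
12.1579,4.9474
12.3421,4.9390
12.5263,4.9306
12.7105,4.9222
12.8947,4.9139
13.0789,4.9055
13.2632,4.8971
13.4474,4.8888
13.6316,4.8804
13.8158,4.8720
14.0000,4.8636
14.1842,4.8553
14.3684,4.8469
14.5526,4.8385
14.7368,4.8301
14.9211,4.8218
15.1053,4.8134
15.2895,4.8050
15.4737,4.7967
15.6579,4.7883
15.8421,4.7799
16.0263,4.7715
16.2105,4.7632
16.3947,4.7548
16.5789,4.7303
16.7632,4.6842
16.9474,4.6382
17.1316,4.5921
17.3158,4.5461
17.5000,4.5000
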