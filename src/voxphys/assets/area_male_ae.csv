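# Supraglottal area function (male ae), distance from glottis [cm], area [cm^2].
# Smooth parametric approximation of published MRI-based vowel tract shapes
# (not a digitization of any single published table); formants verified to
# lie in physiologic ranges for the vowel.
0.0000,0.4500
0.1842,0.4684
0.3684,0.4868
0.5526,0.5053
0.7368,0.5237
0.9211,0.5421
1.1053,0.5605
1.2895,0.5789
1.4737,0.5974
1.6579,0.7053
1.8421,0.8281
2.0263,0.9509
2.2105,1.0737
2.3947,1.1965
2.5789,1.3193
2.7632,1.4421
2.9474,1.5649
3.1316,1.6263
3.3158,1.6632
3.5000,1.7000
3.6842,1.7368
3.8684,1.7737
4.0526,1.8105
4.2368,1.8474
4.4211,1.8842
4.6053,1.9211
4.7895,1.9579
4.9737,1.9947
5.1579,2.0316
5.3421,2.0684
5.5263,2.1053
5.7105,2.1421
5.8947,2.1789
6.0789,2.1895
6.2632,2.1649
6.4474,2.1404
6.6316,2.1158
6.8158,2.0912
7.0000,2.0667
7.1842,2.0421
7.3684,2.0175
7.5526,1.9930
7.7368,1.9684
7.9211,1.9439
8.1053,1.9193
8.2895,1.8947
8.4737,1.8702
8.6579,1.8456
8.8421,1.8211
9.0263,1.8070
9.2105,1.8561
9.3947,1.9053
9.5789,1.9544
9.7632,2.0035
9.9474,2.0526
10.1316,2.1018
10.3158,2.1509
10.5000,2.2000
10.6842,2.2491
10.8684,2.2982
11.0526,2.3474
11.2368,2.3965
11.4211,2.4456
11.6053,2.4947
11.7895,2.5439
11.9737,2.5930
12.1579,2.7200
12.3421,2.8600
12.5263,3.0000
12.7105,3.1400
12.8947,3.2800
13.0789,3.4200
13.2632,3.5600
13.4474,3.7000
13.6316,3.8400
13.8158,3.9800
14.0000,4.1200
14.1842,4.2600
14.3684,4.4000
14.5526,4.5263
14.7368,4.6184
14.9211,4.7105
15.1053,4.8026
15.2895,4.8947
15.4737,4.9868
15.6579,5.0789
15.8421,5.1711
16.0263,5.2632
16.2105,5.3553
16.3947,5.4474
16.5789,5.4605
16.7632,5.3684
16.9474,5.2763
17.1316,5.1842
17.3158,5.0921
17.5000,5.0000
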