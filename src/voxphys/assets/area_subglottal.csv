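# Subglottal (tracheal) area function, distance from glottis [cm], area [cm^2].
# Representative adult trachea; approximate, not digitized from a table.
0.0000,1.5000
0.1964,1.6964
0.3927,1.8927
0.5891,2.0261
0.7855,2.1570
0.9818,2.2879
1.1782,2.3356
1.3745,2.3749
1.5709,2.4142
1.7673,2.4535
1.9636,2.4927
2.1600,2.5000
2.3564,2.5000
2.5527,2.5000
2.7491,2.5000
2.9455,2.5000
3.1418,2.5000
3.3382,2.5000
3.5345,2.5000
3.7309,2.5000
3.9273,2.5000
4.1236,2.5000
4.3200,2.5000
4.5164,2.5000
4.7127,2.5000
4.9091,2.5000
5.1055,2.5000
5.3018,2.5000
5.4982,2.5000
5.6945,2.5000
5.8909,2.5000
6.0873,2.5000
6.2836,2.5000
6.4800,2.5000
6.6764,2.5000
6.8727,2.5000
7.0691,2.5000
7.2655,2.5000
7.4618,2.5000
7.6582,2.5000
7.8545,2.5000
8.0509,2.5000
8.2473,2.5000
8.4436,2.5000
8.6400,2.5000
8.8364,2.5000
9.0327,2.5000
9.2291,2.5000
9.4255,2.5000
9.6218,2.5000
9.8182,2.5000
10.0145,2.5000
10.2109,2.5000
10.4073,2.5000
10.6036,2.5000
10.8000,2.5000
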