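r,g,b
0.2081,0.1663,0.5292
0.2090,0.1721,0.5412
0.2098,0.1779,0.5532
0.2107,0.1837,0.5651
0.2116,0.1895,0.5771
0.2118,0.1954,0.5893
0.2119,0.2014,0.6015
0.2121,0.2073,0.6137
0.2123,0.2132,0.6258
0.2114,0.2193,0.6382
0.2103,0.2255,0.6506
0.2093,0.2316,0.6630
0.2082,0.2377,0.6753
0.2055,0.2441,0.6879
0.2025,0.2505,0.7004
0.1995,0.2569,0.7130
0.1965,0.2633,0.7255
0.1909,0.2700,0.7382
0.1846,0.2767,0.7508
0.1784,0.2835,0.7635
0.1722,0.2903,0.7762
0.1622,0.2980,0.7888
0.1509,0.3060,0.8014
0.1397,0.3139,0.8141
0.1285,0.3219,0.8267
0.1136,0.3305,0.8370
0.0973,0.3393,0.8464
0.0809,0.3481,0.8558
0.0646,0.3569,0.8652
0.0513,0.3644,0.8706
0.0396,0.3712,0.8739
0.0279,0.3780,0.8773
0.0162,0.3849,0.8807
0.0108,0.3907,0.8821
0.0094,0.3959,0.8823
0.0080,0.4012,0.8825
0.0066,0.4064,0.8827
0.0075,0.4111,0.8822
0.0101,0.4156,0.8812
0.0127,0.4200,0.8801
0.0153,0.4245,0.8791
0.0186,0.4287,0.8777
0.0227,0.4328,0.8761
0.0267,0.4368,0.8745
0.0308,0.4409,0.8729
0.0349,0.4448,0.8711
0.0391,0.4487,0.8691
0.0432,0.4525,0.8672
0.0474,0.4564,0.8652
0.0512,0.4602,0.8632
0.0544,0.4639,0.8610
0.0577,0.4677,0.8589
0.0609,0.4714,0.8567
0.0638,0.4751,0.8546
0.0661,0.4788,0.8524
0.0684,0.4825,0.8503
0.0708,0.4862,0.8481
0.0728,0.4900,0.8460
0.0741,0.4937,0.8440
0.0755,0.4975,0.8419
0.0769,0.5013,0.8399
0.0780,0.5051,0.8379
0.0783,0.5091,0.8361
0.0787,0.5130,0.8343
0.0790,0.5170,0.8326
0.0790,0.5210,0.8309
0.0780,0.5254,0.8297
0.0769,0.5297,0.8285
0.0758,0.5340,0.8273
0.0744,0.5384,0.8262
0.0717,0.5432,0.8256
0.0691,0.5481,0.8251
0.0664,0.5529,0.8245
0.0636,0.5577,0.8240
0.0598,0.5627,0.8237
0.0560,0.5677,0.8234
0.0522,0.5727,0.8231
0.0485,0.5777,0.8227
0.0449,0.5824,0.8220
0.0413,0.5872,0.8213
0.0377,0.5920,0.8206
0.0342,0.5968,0.8198
0.0323,0.6010,0.8182
0.0304,0.6053,0.8167
0.0284,0.6095,0.8151
0.0265,0.6137,0.8135
0.0259,0.6174,0.8111
0.0252,0.6211,0.8087
0.0246,0.6248,0.8063
0.0239,0.6285,0.8039
0.0237,0.6318,0.8009
0.0235,0.6350,0.7978
0.0233,0.6383,0.7947
0.0231,0.6415,0.7916
0.0230,0.6444,0.7881
0.0230,0.6473,0.7845
0.0229,0.6502,0.7809
0.0228,0.6531,0.7773
0.0236,0.6558,0.7734
0.0246,0.6584,0.7694
0.0256,0.6611,0.7654
0.0265,0.6637,0.7615
0.0290,0.6662,0.7573
0.0319,0.6687,0.7531
0.0348,0.6712,0.7488
0.0377,0.6737,0.7446
0.0423,0.6761,0.7402
0.0474,0.6784,0.7357
0.0525,0.6808,0.7312
0.0575,0.6831,0.7267
0.0635,0.6854,0.7220
0.0697,0.6876,0.7173
0.0760,0.6898,0.7125
0.0822,0.6921,0.7078
0.0891,0.6942,0.7029
0.0962,0.6964,0.6978
0.1034,0.6985,0.6928
0.1106,0.7007,0.6878
0.1182,0.7028,0.6826
0.1261,0.7048,0.6774
0.1340,0.7069,0.6721
0.1419,0.7089,0.6669
0.1502,0.7109,0.6615
0.1588,0.7129,0.6560
0.1674,0.7148,0.6505
0.1760,0.7168,0.6450
0.1850,0.7186,0.6394
0.1943,0.7204,0.6337
0.2036,0.7223,0.6280
0.2129,0.7241,0.6223
0.2226,0.7258,0.6165
0.2327,0.7274,0.6106
0.2428,0.7291,0.6047
0.2528,0.7308,0.5988
0.2632,0.7323,0.5928
0.2740,0.7338,0.5869
0.2848,0.7352,0.5809
0.2955,0.7367,0.5749
0.3065,0.7381,0.5690
0.3179,0.7392,0.5630
0.3293,0.7404,0.5571
0.3406,0.7416,0.5512
0.3521,0.7427,0.5454
0.3637,0.7436,0.5398
0.3754,0.7444,0.5341
0.3870,0.7453,0.5284
0.3986,0.7461,0.5229
0.4101,0.7466,0.5177
0.4217,0.7471,0.5125
0.4332,0.7477,0.5073
0.4447,0.7482,0.5022
0.4558,0.7484,0.4974
0.4669,0.7487,0.4926
0.4781,0.7489,0.4879
0.4891,0.7491,0.4832
0.4997,0.7491,0.4787
0.5103,0.7491,0.4743
0.5209,0.7491,0.4699
0.5314,0.7491,0.4655
0.5415,0.7489,0.4614
0.5517,0.7488,0.4573
0.5618,0.7486,0.4531
0.5718,0.7485,0.4490
0.5815,0.7482,0.4452
0.5911,0.7479,0.4413
0.6007,0.7476,0.4374
0.6103,0.7473,0.4335
0.6196,0.7469,0.4298
0.6288,0.7464,0.4262
0.6381,0.7460,0.4225
0.6473,0.7456,0.4188
0.6562,0.7451,0.4152
0.6651,0.7446,0.4117
0.6741,0.7440,0.4081
0.6830,0.7435,0.4046
0.6916,0.7429,0.4011
0.7003,0.7423,0.3977
0.7089,0.7417,0.3943
0.7176,0.7412,0.3908
0.7260,0.7405,0.3874
0.7344,0.7398,0.3841
0.7429,0.7392,0.3807
0.7513,0.7385,0.3773
0.7596,0.7378,0.3739
0.7678,0.7371,0.3706
0.7760,0.7364,0.3673
0.7842,0.7357,0.3639
0.7923,0.7350,0.3606
0.8004,0.7343,0.3573
0.8085,0.7336,0.3539
0.8166,0.7329,0.3506
0.8246,0.7322,0.3472
0.8325,0.7315,0.3438
0.8405,0.7308,0.3404
0.8484,0.7301,0.3370
0.8563,0.7295,0.3335
0.8641,0.7288,0.3299
0.8720,0.7282,0.3264
0.8798,0.7276,0.3229
0.8876,0.7271,0.3192
0.8954,0.7267,0.3154
0.9032,0.7263,0.3116
0.9109,0.7260,0.3077
0.9187,0.7258,0.3036
0.9263,0.7259,0.2992
0.9340,0.7260,0.2948
0.9417,0.7261,0.2905
0.9491,0.7268,0.2855
0.9562,0.7282,0.2801
0.9634,0.7295,0.2746
0.9705,0.7308,0.2692
0.9765,0.7332,0.2632
0.9814,0.7367,0.2567
0.9863,0.7402,0.2502
0.9912,0.7437,0.2437
0.9944,0.7478,0.2375
0.9957,0.7527,0.2316
0.9970,0.7576,0.2257
0.9983,0.7625,0.2198
0.9986,0.7675,0.2143
0.9978,0.7726,0.2094
0.9969,0.7778,0.2046
0.9960,0.7829,0.1997
0.9948,0.7880,0.1951
0.9929,0.7931,0.1908
0.9911,0.7982,0.1865
0.9892,0.8032,0.1822
0.9873,0.8083,0.1781
0.9850,0.8134,0.1741
0.9828,0.8184,0.1701
0.9805,0.8235,0.1661
0.9783,0.8286,0.1622
0.9760,0.8338,0.1583
0.9737,0.8390,0.1544
0.9714,0.8441,0.1505
0.9693,0.8494,0.1465
0.9675,0.8550,0.1424
0.9658,0.8605,0.1383
0.9640,0.8660,0.1342
0.9624,0.8716,0.1301
0.9615,0.8777,0.1257
0.9606,0.8837,0.1213
0.9597,0.8897,0.1169
0.9589,0.8958,0.1126
0.9592,0.9025,0.1080
0.9594,0.9091,0.1035
0.9596,0.9158,0.0989
0.9599,0.9225,0.0943
0.9615,0.9298,0.0896
0.9631,0.9371,0.0848
0.9646,0.9444,0.0800
0.9662,0.9518,0.0752
0.9687,0.9596,0.0699
0.9713,0.9674,0.0645
0.9738,0.9753,0.0592
0.9763,0.9831,0.0538
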