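age_years,M,S,L
0.0383,8.81,0.3126,1.3917
0.0575,10.59,0.2801,1.4418
0.0767,12.27,0.2526,1.4891
0.0958,13.87,0.2291,1.5331
0.1150,15.39,0.2089,1.5722
0.1342,16.83,0.1916,1.6049
0.1533,18.20,0.1767,1.6304
0.1725,19.50,0.1640,1.6487
0.1916,20.75,0.1531,1.6607
0.2108,21.94,0.1436,1.6676
0.2300,23.07,0.1354,1.6706
0.2491,24.16,0.1283,1.6711
0.2683,25.21,0.1220,1.6698
0.2875,26.21,0.1165,1.6673
0.3066,27.17,0.1117,1.6636
0.3258,28.10,0.1074,1.6589
0.3450,28.99,0.1035,1.6533
0.3641,29.86,0.1001,1.6471
0.3833,30.70,0.0970,1.6403
0.4025,31.50,0.0942,1.6330
0.4216,32.29,0.0917,1.6255
0.4408,33.05,0.0894,1.6178
0.4600,33.79,0.0873,1.6100
0.4791,34.51,0.0854,1.6022
0.4983,35.21,0.0837,1.5946
0.5175,35.89,0.0821,1.5870
0.5366,36.55,0.0807,1.5797
0.5558,37.20,0.0793,1.5725
0.5749,37.83,0.0781,1.5656
0.5941,38.44,0.0770,1.5588
0.6133,39.04,0.0759,1.5523
0.6324,39.63,0.0749,1.5460
0.6516,40.21,0.0740,1.5399
0.6708,40.77,0.0731,1.5340
0.6899,41.32,0.0723,1.5284
0.7091,41.86,0.0715,1.5230
0.7283,42.39,0.0707,1.5178
0.7474,42.91,0.0700,1.5128
0.7666,43.42,0.0693,1.5081
0.7858,43.92,0.0687,1.5036
0.8049,44.40,0.0681,1.4993
0.8241,44.88,0.0674,1.4952
0.8433,45.36,0.0669,1.4913
0.8624,45.82,0.0663,1.4876
0.8816,46.27,0.0657,1.4841
0.9008,46.72,0.0652,1.4809
0.9199,47.16,0.0647,1.4778
0.9391,47.59,0.0642,1.4749
0.9582,48.01,0.0637,1.4723
0.9774,48.43,0.0632,1.4698
0.9966,48.84,0.0627,1.4676
1.0157,49.24,0.0622,1.4655
1.0349,49.64,0.0618,1.4637
1.0541,50.03,0.0613,1.4620
1.0732,50.41,0.0608,1.4605
1.0924,50.79,0.0604,1.4592
1.1116,51.16,0.0600,1.4580
1.1307,51.53,0.0595,1.4570
1.1499,51.89,0.0591,1.4561
1.1691,52.24,0.0587,1.4553
1.1882,52.59,0.0583,1.4547
1.2074,52.94,0.0578,1.4542
1.2266,53.27,0.0574,1.4538
1.2457,53.61,0.0570,1.4535
1.2649,53.94,0.0566,1.4534
1.2841,54.26,0.0562,1.4533
1.3032,54.58,0.0559,1.4533
1.3224,54.89,0.0555,1.4533
1.3415,55.20,0.0551,1.4535
1.3607,55.50,0.0547,1.4537
1.3799,55.81,0.0544,1.4539
1.3990,56.10,0.0540,1.4542
1.4182,56.39,0.0536,1.4546
1.4374,56.68,0.0533,1.4551
1.4565,56.97,0.0530,1.4555
1.4757,57.25,0.0526,1.4561
1.4949,57.52,0.0523,1.4567
1.5140,57.80,0.0520,1.4573
1.5332,58.06,0.0517,1.4580
1.5524,58.33,0.0514,1.4587
1.5715,58.59,0.0510,1.4595
1.5907,58.85,0.0508,1.4603
1.6099,59.11,0.0505,1.4612
1.6290,59.36,0.0502,1.4620
1.6482,59.61,0.0499,1.4630
1.6674,59.86,0.0496,1.4639
1.6865,60.11,0.0494,1.4649
1.7057,60.35,0.0491,1.4660
1.7248,60.59,0.0488,1.4670
1.7440,60.82,0.0486,1.4681
1.7632,61.06,0.0483,1.4692
1.7823,61.29,0.0481,1.4704
1.8015,61.52,0.0478,1.4716
1.8207,61.75,0.0476,1.4728
1.8398,61.97,0.0474,1.4740
1.8590,62.20,0.0471,1.4752
1.8782,62.42,0.0469,1.4765
1.8973,62.64,0.0467,1.4778
1.9165,62.85,0.0465,1.4791
1.9357,63.07,0.0463,1.4805
1.9548,63.28,0.0461,1.4818
1.9740,63.49,0.0459,1.4832
1.9932,63.70,0.0457,1.4846
2.0123,63.91,0.0455,1.4861
2.0315,64.11,0.0453,1.4875
2.0507,64.32,0.0451,1.4890
2.0698,64.52,0.0449,1.4904
2.0890,64.72,0.0447,1.4919
2.1081,64.92,0.0445,1.4934
2.1273,65.11,0.0443,1.4949
2.1465,65.31,0.0441,1.4964
2.1656,65.50,0.0440,1.4979
2.1848,65.70,0.0438,1.4994
2.2040,65.89,0.0436,1.5009
2.2231,66.08,0.0434,1.5024
2.2423,66.26,0.0433,1.5039
2.2615,66.45,0.0431,1.5054
2.2806,66.64,0.0429,1.5069
2.2998,66.82,0.0428,1.5084
2.3190,67.00,0.0426,1.5098
2.3381,67.18,0.0425,1.5113
2.3573,67.36,0.0423,1.5127
2.3765,67.54,0.0421,1.5142
2.3956,67.72,0.0420,1.5156
2.4148,67.89,0.0418,1.5170
2.4339,68.07,0.0417,1.5185
2.4531,68.24,0.0415,1.5199
2.4723,68.41,0.0414,1.5213
2.4914,68.59,0.0412,1.5226
2.5106,68.75,0.0411,1.5240
2.5298,68.92,0.0410,1.5254
2.5489,69.09,0.0408,1.5267
2.5681,69.26,0.0407,1.5281
2.5873,69.42,0.0405,1.5294
2.6064,69.59,0.0404,1.5308
2.6256,69.75,0.0403,1.5321
2.6448,69.91,0.0401,1.5334
2.6639,70.07,0.0400,1.5347
2.6831,70.23,0.0399,1.5360
2.7023,70.39,0.0397,1.5373
2.7214,70.55,0.0396,1.5386
2.7406,70.71,0.0395,1.5398
2.7598,70.86,0.0394,1.5411
2.7789,71.02,0.0392,1.5423
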