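genotype,E1,E2,E3,E4,E5,E6,E7,E8,E9,E10,E11,E12
G1,9887,9683,5896,8300,4833,10321,5752,6826,6807,6317,6634,3913
G2,9687,9233,6127,7117,4167,11776,3870,6582,7017,6477,6559,3048
G3,9831,8517,6150,7392,3667,12144,4722,6641,7017,6113,6838,4077
G4,9580,8850,6108,6558,4167,8745,4952,6894,6990,6050,6836,3872
G5,8672,7958,5761,6083,3333,8502,5504,6948,7240,5980,6713,4201
G6,9533,9625,6087,7500,4500,7430,5390,6497,7130,6210,6540,3707
G7,9118,8008,5584,5683,3500,11795,4837,6670,7180,6080,6842,3039
G8,7774,8167,5891,6275,3667,10448,4098,6929,7373,5987,6963,3212
G9,10226,10800,5982,8300,5333,10531,5393,7033,7157,6573,6674,3871
G10,9257,8283,6115,5958,5333,11330,6451,6266,7067,5517,6378,3962
G11,9215,8408,5828,5567,4833,9741,6717,6477,6823,6050,6403,4135
G12,7836,9483,5986,6767,4167,9460,5969,6584,6997,6387,6763,4110
G13,7805,8917,6191,6067,4333,12505,5662,6488,6947,6327,6374,4720
G14,8103,8750,6314,6675,4667,11598,5053,6718,6623,5717,6882,3089
G15,6605,5875,4811,5058,3167,8618,5862,7338,7090,6147,7561,2998
G16,9015,10633,6101,7933,3000,9432,5970,7915,7030,6027,8284,3212
G17,8267,6633,5459,7075,3167,7259,5108,7064,6547,6397,6436,2636
G18,8944,6408,5145,6133,3500,7636,6038,6083,6800,6566,6074,3954
G19,8205,7717,5847,7883,4833,7357,6559,6531,7307,6497,6706,4736
G20,8574,5517,4628,5633,5667,10263,6318,6622,6217,6420,6710,4448
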