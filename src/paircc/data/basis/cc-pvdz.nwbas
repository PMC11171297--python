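# cc-pVDZ-style correlation-consistent basis
# Exponents: published Dunning correlation-consistent values.
# General-contraction coefficients regenerated by spherically
# averaged atomic HF in the uncontracted primitive basis
# (scripts/make_cc_basis.py).
H s
       13.010000  -0.0196850445
        1.962000  -0.1379770288
        0.444600  -0.4781480655
        0.122000  -0.5012393363
H s
        0.122000   1.0
H p
        0.727000   1.0
He s
       38.360000  -0.0238088239
        5.770000  -0.1548911896
        1.240000  -0.4699868197
        0.297600  -0.5130267602
He s
        0.297600   1.0
He p
        1.275000   1.0
Li s
     1469.000000  -0.0007659708  -0.0001006362
      220.500000  -0.0058940576  -0.0007850302
       50.260000  -0.0296793283  -0.0039173121
       14.240000  -0.1092345586  -0.0151445924
        4.581000  -0.2828806177  -0.0403091097
        1.580000  -0.4533324733  -0.0838408828
        0.564000  -0.2746550471  -0.1064194275
        0.073450  -0.0091419925   0.2953344276
        0.028050   0.0034042172   0.7714948907
Li s
        0.028050   1.0
Li p
        1.534000   1.0
Li p
        0.274900   1.0
Li p
        0.073620   1.0
Li p
        0.024030   1.0
Li d
        0.123900   1.0
C s
     6665.000000  -0.0007048456  -0.0001525731
     1000.000000  -0.0051774921  -0.0011427250
      228.000000  -0.0282054696  -0.0061383423
       64.710000  -0.0955959723  -0.0222587925
       21.060000  -0.3056501398  -0.0742003973
        6.459000  -0.5015549199  -0.1790983575
        2.525000  -0.2034933270  -0.0948524307
        0.521500  -0.0193366737   0.5758267027
        0.159600   0.0052573305   0.5505215256
C s
        0.159600   1.0
C p
        9.439000   0.0327170815
        2.002000   0.1847022966
        0.545600   0.4084094579
        0.151700   0.5945434959
C p
        0.151700   1.0
C d
        0.550000   1.0
N s
     9046.000000  -0.0006999791  -0.0001555551
     1357.000000  -0.0053921501  -0.0012328676
      309.300000  -0.0274152052  -0.0060974821
       87.730000  -0.1032716942  -0.0250770583
       28.560000  -0.2787943228  -0.0685786405
       10.210000  -0.4492495901  -0.1625469682
        3.838000  -0.2776027489  -0.1224516247
        0.746600  -0.0147037583   0.5786120377
        0.224800   0.0026844102   0.5514576725
N s
        0.224800   1.0
N p
       13.550000  -0.0364918895
        2.917000  -0.2017363949
        0.797300  -0.4421819828
        0.218500  -0.5492703095
N p
        0.218500   1.0
N d
        0.817000   1.0
O s
    11720.000000  -0.0007105993  -0.0001613180
     1759.000000  -0.0054722391  -0.0012776650
      400.800000  -0.0278432600  -0.0063306739
      113.700000  -0.1048411419  -0.0260341328
       37.030000  -0.2831160601  -0.0716131161
       13.270000  -0.4491591553  -0.1680817125
        5.025000  -0.2705413138  -0.1171926903
        1.013000  -0.0150204772   0.5744295983
        0.302300   0.0024828311   0.5569892006
O s
        0.302300   1.0
O p
       17.700000  -0.0411340665
        3.854000  -0.2201850632
        1.046000  -0.4780912087
        0.275300  -0.5024824873
O p
        0.275300   1.0
O d
        1.185000   1.0
F s
    14710.000000  -0.0007253631  -0.0001710658
     2207.000000  -0.0054990215  -0.0012474304
      502.800000  -0.0287490716  -0.0070104547
      140.600000  -0.1072065684  -0.0248733901
       46.970000  -0.2770752996  -0.0804340007
       17.350000  -0.4308562568  -0.1312471685
        6.870000  -0.2825578543  -0.1943308614
        1.750000  -0.0234446075   0.5321872503
        0.366900   0.0019770671   0.6654656504
F s
        0.366900   1.0
F p
       22.670000  -0.0441774443
        4.977000  -0.2328486048
        1.347000  -0.4986247909
        0.347100  -0.4720568665
F p
        0.347100   1.0
F d
        1.640000   1.0
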