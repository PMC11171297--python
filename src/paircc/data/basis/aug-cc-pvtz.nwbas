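# aug-cc-pVTZ-style correlation-consistent basis
# Exponents: published Dunning correlation-consistent values.
# General-contraction coefficients regenerated by spherically
# averaged atomic HF in the uncontracted primitive basis
# (scripts/make_cc_basis.py).
H s
       33.870000  -0.0060681302
        5.095000  -0.0453076239
        1.159000  -0.2028215944
        0.325800  -0.5039036442
        0.102700  -0.3834206461
H s
        0.325800   1.0
H s
        0.102700   1.0
H s
        0.025260   1.0
H p
        1.407000   1.0
H p
        0.388000   1.0
H p
        0.102000   1.0
H d
        1.057000   1.0
H d
        0.247000   1.0
F s
    19500.000000  -0.0005072814   0.0001178051
     2923.000000  -0.0039232792   0.0009178108
      664.500000  -0.0202026079   0.0047317549
      187.500000  -0.0790214646   0.0192383343
       60.620000  -0.2304743408   0.0597421421
       21.420000  -0.4330027579   0.1416654642
        7.950000  -0.3499868862   0.1757535109
        2.257000  -0.0427869250  -0.1667143628
        0.881500   0.0075523224  -0.6356906963
        0.285700  -0.0021838653  -0.3455980633
F s
        0.881500   1.0
F s
        0.285700   1.0
F s
        0.107600   1.0
F p
       43.880000  -0.0163991361
        9.926000  -0.1025131995
        2.930000  -0.3120900640
        0.913200  -0.4771285845
        0.267200  -0.3544982735
F p
        0.913200   1.0
F p
        0.267200   1.0
F p
        0.073610   1.0
F d
        3.107000   1.0
F d
        0.855000   1.0
F d
        0.292000   1.0
F f
        1.917000   1.0
F f
        0.724000   1.0
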