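# STO-3G minimal basis, standard published Slater-zeta scaling
# (Hehre, Stewart, Pople fits; alpha_i = zeta^2 * alpha_i^(zeta=1))
H s
  3.42525091  0.15432897
  0.62391373  0.53532814
  0.16885616  0.44463454
He s
  6.36242139  0.15432897
  1.15892300  0.53532814
  0.31365119  0.44463454
Li s
  16.11957475  0.15432897
  2.93620066  0.53532814
  0.79465403  0.44463454
Li s
  0.63628992  -0.09996723
  0.14785984  0.39951283
  0.04808870  0.70011547
Li p
  0.63628992  0.15591627
  0.14785984  0.60768372
  0.04808870  0.39195739
Be s
  30.16787069  0.15432897
  5.49511530  0.53532814
  1.48719928  0.44463454
Be s
  1.31483347  -0.09996723
  0.30553850  0.39951283
  0.09937080  0.70011547
Be p
  1.31483347  0.15591627
  0.30553850  0.60768372
  0.09937080  0.39195739
B s
  48.79111318  0.15432897
  8.88736217  0.53532814
  2.40527776  0.44463454
B s
  2.23695675  -0.09996723
  0.51981975  0.39951283
  0.16906185  0.70011547
B p
  2.23695675  0.15591627
  0.51981975  0.60768372
  0.16906185  0.39195739
C s
  71.61683735  0.15432897
  13.04509632  0.53532814
  3.53052790  0.44463454
C s
  2.94125016  -0.09996723
  0.68348211  0.39951283
  0.22229003  0.70011547
C p
  2.94125016  0.15591627
  0.68348211  0.60768372
  0.22229003  0.39195739
N s
  99.10616896  0.15432897
  18.05231238  0.53532814
  4.88568202  0.44463454
N s
  3.78045691  -0.09996723
  0.87849538  0.39951283
  0.28571453  0.70011547
N p
  3.78045691  0.15591627
  0.87849538  0.60768372
  0.28571453  0.39195739
O s
  130.70932136  0.15432897
  23.80886604  0.53532814
  6.44363704  0.44463454
O s
  5.03315269  -0.09996723
  1.16959444  0.39951283
  0.38038916  0.70011547
O p
  5.03315269  0.15591627
  1.16959444  0.60768372
  0.38038916  0.39195739
F s
  166.67913405  0.15432897
  30.36081232  0.53532814
  8.21685730  0.44463454
F s
  6.46480501  -0.09996723
  1.50227908  0.39951283
  0.48858875  0.70011547
F p
  6.46480501  0.15591627
  1.50227908  0.60768372
  0.48858875  0.39195739
Ne s
  207.01560701  0.15432897
  37.70815122  0.53532814
  10.20534281  0.44463454
Ne s
  8.24631736  -0.09996723
  1.91626353  0.39951283
  0.62322960  0.70011547
Ne p
  8.24631736  0.15591627
  1.91626353  0.60768372
  0.62322960  0.39195739
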