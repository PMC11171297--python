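&FCI NORB=2,NELEC=2,MS2=0,
ORBSYM=1,1,
ISYM=1,
/
  6.7459422983913242e-01    1    1    1    1
  1.8125807715156744e-01    2    1    2    1
  6.6356384359168807e-01    2    2    1    1
  6.9749488786677560e-01    2    2    2    2
 -1.2527961177101226e+00    1    1    0    0
 -4.7560381194047263e-01    2    2    0    0
  7.1428387787001424e-01    0    0    0    0
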