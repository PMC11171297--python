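&FCI NORB=4,NELEC=4,MS2=0,
ORBSYM=1,1,1,1,
ISYM=1,
/
 -3.4999999999999998e-01    1    1    1    1
 -3.4999999999999998e-01    2    1    2    1
 -1.7499999999999999e-01    2    2    1    1
 -3.4999999999999998e-01    2    2    2    2
 -3.4999999999999998e-01    3    1    3    1
 -3.4999999999999998e-01    3    2    3    2
 -1.7499999999999999e-01    3    3    1    1
 -1.7499999999999999e-01    3    3    2    2
 -3.4999999999999998e-01    3    3    3    3
 -3.4999999999999998e-01    4    1    4    1
 -3.4999999999999998e-01    4    2    4    2
 -3.4999999999999998e-01    4    3    4    3
 -1.7499999999999999e-01    4    4    1    1
 -1.7499999999999999e-01    4    4    2    2
 -1.7499999999999999e-01    4    4    3    3
 -3.4999999999999998e-01    4    4    4    4
  1.0000000000000000e+00    2    2    0    0
  2.2000000000000002e+00    3    3    0    0
  3.1000000000000001e+00    4    4    0    0
  0.0000000000000000e+00    0    0    0    0
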