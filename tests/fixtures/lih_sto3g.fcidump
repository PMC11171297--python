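&FCI NORB=6,NELEC=4,MS2=0,
ORBSYM=1,1,1,1,1,1,
ISYM=1,
/
  1.6585543455762357e+00    1    1    1    1
  1.1190871940216403e-01    2    1    1    1
  1.3388485399072008e-02    2    1    2    1
  3.6722466519599356e-01    2    2    1    1
 -6.2515665348228423e-03    2    2    2    1
  4.8760930537541636e-01    2    2    2    2
 -1.3853805151166990e-01    3    1    1    1
 -1.1228316929690110e-02    3    1    2    1
 -1.5917624304343070e-02    3    1    2    2
  2.1656569640623922e-02    3    1    3    1
 -1.3360834237145689e-02    3    2    1    1
 -3.3612553950212818e-03    3    2    2    1
  4.8506727913640357e-02    3    2    2    2
 -1.7881357588754940e-04    3    2    3    1
  1.3020922450390167e-02    3    2    3    2
  3.9565100233113076e-01    3    3    1    1
  1.1060556214387169e-02    3    3    2    1
  2.2373294584432013e-01    3    3    2    2
  1.8319998949535012e-03    3    3    3    1
 -7.4274487754751083e-03    3    3    3    2
  3.3792759973166636e-01    3    3    3    3
  9.8179000221540417e-03    4    1    4    1
 -1.2726003800550694e-16    4    2    2    2
 -7.4919385864212970e-03    4    2    4    1
  2.3446261361196246e-02    4    2    4    2
 -1.1813597765732625e-16    4    3    1    1
  1.0256973699952123e-02    4    3    4    1
 -1.9273197753283983e-02    4    3    4    2
  4.1277618781143922e-02    4    3    4    3
  3.9631873069222023e-01    4    4    1    1
  4.3653317121496700e-03    4    4    2    1
  2.7038353631622086e-01    4    4    2    2
 -4.9739889514057826e-03    4    4    3    1
 -5.7205405800813776e-03    4    4    3    2
  2.8200190883496878e-01    4    4    3    3
 -1.1645264102242008e-16    4    4    4    3
  3.1294529296001949e-01    4    4    4    4
  9.8179000221540417e-03    5    1    5    1
 -7.4919385864212987e-03    5    2    5    1
  2.3446261361196249e-02    5    2    5    2
  1.0256973699952127e-02    5    3    5    1
 -1.9273197753283986e-02    5    3    5    2
  4.1277618781143929e-02    5    3    5    3
  1.6869127844918376e-02    5    4    5    4
  3.9631873069222034e-01    5    5    1    1
  4.3653317121496883e-03    5    5    2    1
  2.7038353631622097e-01    5    5    2    2
 -4.9739889514057965e-03    5    5    3    1
 -5.7205405800813810e-03    5    5    3    2
  2.8200190883496884e-01    5    5    3    3
  2.7920703727018270e-01    5    5    4    4
  3.1294529296001961e-01    5    5    5    5
  5.2695602003147962e-02    6    1    1    1
  8.8823815531702561e-03    6    1    2    1
 -6.8094641266403825e-03    6    1    2    2
 -2.3153439615751737e-03    6    1    3    1
 -1.6726002102413168e-03    6    1    3    2
  1.0413077661709780e-02    6    1    3    3
  5.7561586181983514e-04    6    1    4    4
  5.7561586181983525e-04    6    1    5    5
  8.4998371446833136e-03    6    1    6    1
  4.0995927779397923e-02    6    2    1    1
  4.7344280386654924e-03    6    2    2    1
 -1.2701624769862427e-01    6    2    2    2
 -5.0974656715894182e-04    6    2    3    1
 -3.4549289552758114e-02    6    2    3    2
  1.2302697632540703e-02    6    2    3    3
  1.6072661091659460e-02    6    2    4    4
  1.6072661091659463e-02    6    2    5    5
 -1.2635547426001365e-04    6    2    6    1
  1.2387985432239648e-01    6    2    6    2
  1.7648559031657043e-02    6    3    1    1
  3.6893083907312630e-03    6    3    2    1
 -5.1344397504039400e-02    6    3    2    2
  4.4001402730877350e-03    6    3    3    1
 -9.3645710896841719e-03    6    3    3    2
  3.5981505893127444e-02    6    3    3    3
  2.2005624247675689e-03    6    3    4    4
  2.2005624247675693e-03    6    3    5    5
  4.3027142078410638e-03    6    3    6    1
  3.1863477355840615e-02    6    3    6    2
  2.6438214037037611e-02    6    3    6    3
 -6.1087781391829400e-03    6    4    4    1
  1.9574764268597989e-02    6    4    4    2
 -1.3730855954224347e-02    6    4    4    3
  1.9714710853769881e-02    6    4    6    4
 -6.1087781391829417e-03    6    5    5    1
  1.9574764268597999e-02    6    5    5    2
 -1.3730855954224352e-02    6    5    5    3
  1.9714710853769888e-02    6    5    6    5
  3.6174098678937278e-01    6    6    1    1
 -3.3104020200124392e-03    6    6    2    1
  4.5401434726675483e-01    6    6    2    2
 -1.1337258084854083e-02    6    6    3    1
  4.3302349124666392e-02    6    6    3    2
  2.4146316762935752e-01    6    6    3    3
 -1.0913462504126535e-16    6    6    4    2
  2.6818490187921079e-01    6    6    4    4
  2.6818490187921090e-01    6    6    5    5
 -3.0336998100936488e-03    6    6    6    1
 -1.3448355395234809e-01    6    6    6    2
 -4.4055708755686179e-02    6    6    6    3
  4.5393454128134403e-01    6    6    6    6
 -4.7282771880528305e+00    1    1    0    0
 -1.0565715287198513e-01    2    1    0    0
 -1.4943068689436840e+00    2    2    0    0
  1.6701204473787415e-01    3    1    0    0
 -3.3013376473062857e-02    3    2    0    0
 -1.1258356985626832e+00    3    3    0    0
  3.6130539378036714e-16    4    2    0    0
  3.4085846885835543e-16    4    3    0    0
 -1.1362016258769201e+00    4    4    0    0
 -1.4445972672716457e-16    5    1    0    0
 -2.1114063295376329e-16    5    3    0    0
 -1.1362016258769203e+00    5    5    0    0
 -3.4342245703495297e-02    6    1    0    0
  5.3906773697118049e-02    6    2    0    0
  3.0527043374347022e-02    6    3    0    0
 -1.1127050567638631e-16    6    4    0    0
 -9.5022465992153238e-01    6    6    0    0
  9.9488101319796973e-01    0    0    0    0
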