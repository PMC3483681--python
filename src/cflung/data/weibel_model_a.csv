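# Symmetric 23-generation dichotomous airway dimension table after Weibel's
# "model A" regularized adult lung.  Generation 0 is the trachea, generation
# 23 the alveolar level; every airway of a generation shares the same
# idealized cylindrical diameter and length.
#
# Provenance: the classical model-A dimensions (tabulated at ~4800 cm^3
# inflation) rescaled isotropically to a reference adult functional residual
# capacity of 3300 cm^3, i.e. all linear dimensions multiplied by
# (3300/4800)^(1/3) ~= 0.8826 -- the standard volume normalization used in
# airway-morphometry and deposition modelling.
# Units: millimetres.
generation,diameter_mm,length_mm
0,15.8866,105.9105
1,10.7676,42.0111
2,7.3255,16.7692
3,4.9425,6.7077
4,3.9716,11.2089
5,3.0891,9.4437
6,2.4712,7.9433
7,2.03,6.7077
8,1.6416,5.6486
9,1.3592,4.766
10,1.1474,4.0599
11,0.962,3.4421
12,0.8385,2.9125
13,0.7237,2.383
14,0.6531,2.03
15,0.5825,1.7652
16,0.5296,1.4563
17,0.4766,1.2444
18,0.4413,1.0326
19,0.4148,0.8738
20,0.3972,0.7325
21,0.3795,0.6178
22,0.3619,0.5207
23,0.3619,0.4413
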