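treatment,temperature_K,k_per_day,k_sd
control,277,8.1477,0.0814
control,281,10.4655,0.2743
control,289,13.8307,0.0381
control,293,17.8547,0.1424
allspice,277,5.5696,0.1429
allspice,281,8.3583,0.1037
allspice,289,13.683,0.5107
allspice,293,14.6404,0.3064
basil,277,3.6157,0.1467
basil,281,7.4565,0.006
basil,289,11.96,0.2746
basil,293,17.9823,0.2802
bay leaf,277,5.0828,0.0143
bay leaf,281,9.314,0.0553
bay leaf,289,12.51,0.2037
bay leaf,293,12.9375,0.2903
black seed,277,6.0303,0.085
black seed,281,7.7736,0.0992
black seed,289,11.884,0.2261
black seed,293,15.0553,0.0468
caraway,277,3.7622,0.1607
caraway,281,5.1103,0.1271
caraway,289,8.2472,0.2125
caraway,293,10.4214,0.2175
cardamom,277,6.8443,0.0288
cardamom,281,9.6445,0.1948
cardamom,289,10.5695,0.03
cardamom,293,13.1264,0.2994
clove,277,3.4777,0.0574
clove,281,5.825,0.1333
clove,289,10.0913,0.3264
clove,293,14.7812,0.5409
garlic,277,3.2008,0.1237
garlic,281,5.0483,0.1234
garlic,289,9.0686,0.2595
garlic,293,12.4118,0.0329
nutmeg,277,5.2189,0.0
nutmeg,281,9.2317,0.4906
nutmeg,289,12.5299,0.0444
nutmeg,293,14.6567,0.3445
onion,277,4.9511,0.3146
onion,281,5.7084,0.4963
onion,289,8.352,0.0031
onion,293,11.6554,0.4791
oregano,277,2.7732,0.1898
oregano,281,2.7478,0.1094
oregano,289,8.8805,0.0506
oregano,293,10.503,0.4606
rosemary,277,5.023,0.2823
rosemary,281,6.6476,0.3802
rosemary,289,11.4884,0.6257
rosemary,293,12.651,0.4627
thyme,277,3.3421,0.2202
thyme,281,3.6951,0.1168
thyme,289,8.1486,0.0084
thyme,293,10.5541,0.1328
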