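treatment,r2_arrhenius,r2_arrhenius_sd,ea_kJ_per_mol,ea_sd,k0_per_day,k0_sd,r2_loglogistic,r2_loglogistic_sd,c_per_C,c_sd,tc_printed_C,tc_sd,tc_sign
control,0.9844,0.0059,31.21,0.46,6400000.0,1200000.0,0.9695,0.0047,0.5695,0.0029,10.081,0.346,negated
allspice,0.9573,0.0226,41.08,0.62,340000000.0,88000000.0,0.9767,0.0222,0.5868,0.002,6.001,0.01,negated
basil,0.955,0.009,62.28,0.46,2300000000000.0,400000000000.0,0.9643,0.0036,0.8323,0.0137,0.311,0.006,negated
bay leaf,0.8416,0.0176,36.73,0.66,52000000.0,14000000.0,0.9011,0.0235,0.4726,0.0115,9.083,0.505,negated
black seed,0.9983,0.0022,38.08,0.05,91000000.0,1400000.0,0.9876,0.0039,0.5542,0.0015,6.377,0.023,negated
caraway,0.9983,0.0009,42.53,0.73,410000000.0,110000000.0,0.9934,0.0001,0.4131,0.0048,4.642,0.246,negated
cardamom,0.8834,0.0294,23.58,1.0,220000.0,91000.0,0.8948,0.0207,0.4976,0.2784,14.118,6.698,unverifiable
clove,0.9867,0.0078,58.18,1.6,400000000000.0,260000000000.0,0.9711,0.0004,0.6747,0.0362,0.655,0.39,negated
garlic,0.9938,0.0006,55.73,1.14,110000000000.0,51000000000.0,0.9866,0.0047,0.5646,0.0017,1.134,0.284,negated
nutmeg,0.9085,0.0246,40.19,0.03,230000000.0,1600000.0,0.9649,0.016,0.5544,0.006,6.774,0.192,negated
onion,0.9576,0.0236,35.34,2.11,28000000.0,24000000.0,0.9262,0.0099,0.4022,0.0273,7.09,0.883,negated
oregano,0.9273,0.0113,64.76,4.56,10000000000000.0,14000000000000.0,0.9481,0.0088,0.5553,0.0411,0.89,0.768,as_printed
rosemary,0.9835,0.004,40.52,0.7,230000000.0,56000000.0,0.958,0.0047,0.7291,0.0256,1.847,0.138,unverifiable
thyme,0.9718,0.0057,52.19,2.37,28000000000.0,25000000000.0,0.9655,0.0064,0.4781,0.0084,1.399,0.488,negated
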