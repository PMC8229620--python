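treatment,time_d,observed,pred_arrhenius,pred_loglogistic,pred_ann
control,0,100.00,100.00,100.00,99.33
control,1,93.63,87.88,87.43,88.46
control,2,82.86,75.75,74.85,74.21
control,3,66.33,63.63,62.28,61.84
control,4,52.72,51.51,49.70,50.61
control,6,24.81,27.26,24.55,29.79
allspice,0,100.00,100.00,100.00,99.29
allspice,1,94.86,90.09,89.44,89.42
allspice,2,73.63,80.18,78.88,75.80
allspice,3,68.95,70.27,68.31,64.39
allspice,4,60.07,60.36,57.75,55.06
allspice,6,37.88,40.55,36.63,41.00
basil,0,100.00,100.00,100.00,95.53
basil,1,94.48,91.16,89.75,82.30
basil,2,80.79,82.32,79.51,71.09
basil,3,71.58,73.49,69.26,63.44
basil,4,66.01,64.65,59.01,56.67
basil,6,43.97,46.97,38.52,41.60
bay leaf,0,100.00,100.00,100.00,100.01
bay leaf,1,93.65,90.57,90.04,90.38
bay leaf,2,77.88,81.15,80.08,77.49
bay leaf,3,64.10,71.72,70.12,66.60
bay leaf,4,56.27,62.29,60.16,57.44
bay leaf,6,30.34,43.44,40.23,42.39
black seed,0,100.00,100.00,100.00,99.50
black seed,1,92.89,90.35,89.82,91.24
black seed,2,80.05,80.71,79.63,80.26
black seed,3,71.70,71.06,69.45,70.40
black seed,4,61.11,61.42,59.26,61.04
black seed,6,43.75,42.13,38.89,42.04
caraway,0,100.00,100.00,100.00,100.19
caraway,1,92.95,93.57,93.12,94.95
caraway,2,86.32,87.14,86.25,87.88
caraway,3,79.74,80.71,79.37,81.18
caraway,4,73.33,74.28,72.49,74.70
caraway,6,61.49,61.42,58.74,61.21
cardamom,0,100.00,100.00,100.00,100.75
cardamom,1,94.69,90.17,89.95,94.03
cardamom,2,83.61,80.34,79.91,84.69
cardamom,3,75.09,70.51,69.86,74.05
cardamom,4,65.17,60.68,59.82,62.98
cardamom,6,42.01,41.02,39.72,41.13
clove,0,100.00,100.00,100.00,99.68
clove,1,86.80,92.50,91.47,91.97
clove,2,80.12,85.00,82.94,82.89
clove,3,68.84,77.49,74.41,75.02
clove,4,62.59,69.99,65.88,67.98
clove,6,45.78,54.99,48.82,55.41
garlic,0,100.00,100.00,100.00,99.24
garlic,1,90.31,93.40,92.58,91.99
garlic,2,79.25,86.79,85.17,82.88
garlic,3,74.82,80.19,77.75,75.88
garlic,4,70.41,73.58,70.34,70.54
garlic,6,54.13,60.37,55.51,60.38
nutmeg,0,100.00,100.00,100.00,99.82
nutmeg,1,90.49,90.22,89.59,89.32
nutmeg,2,78.77,80.45,79.18,75.74
nutmeg,3,66.71,70.67,68.77,64.37
nutmeg,4,52.19,60.89,58.36,54.90
nutmeg,6,31.08,41.34,37.55,39.34
onion,0,100.00,100.00,100.00,99.14
onion,1,93.09,92.71,92.34,93.40
onion,2,86.03,85.42,84.68,85.17
onion,3,72.82,78.14,77.01,77.76
onion,4,71.80,70.85,69.35,71.03
onion,6,52.70,56.27,54.03,56.89
oregano,0,100.00,100.00,100.00,99.33
oregano,1,95.52,94.77,93.85,94.41
oregano,2,93.48,89.54,87.69,88.29
oregano,3,82.18,84.31,81.54,82.86
oregano,4,80.58,79.08,75.39,77.80
oregano,6,61.29,68.62,63.08,67.71
rosemary,0,100.00,100.00,100.00,99.33
rosemary,1,94.15,91.59,91.05,90.19
rosemary,2,82.97,83.18,82.10,78.16
rosemary,3,79.21,74.77,73.15,69.60
rosemary,4,64.46,66.36,64.20,63.01
rosemary,6,42.22,49.54,46.30,50.37
thyme,0,100.00,100.00,100.00,100.56
thyme,1,95.51,94.23,93.59,95.26
thyme,2,93.51,88.46,87.19,88.58
thyme,3,91.51,82.70,80.78,82.85
thyme,4,81.33,76.93,74.38,77.29
thyme,6,69.08,65.39,61.57,64.46
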