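segment,layer,l_cm,A_cm2,volume_cm3,vol_perfusion_mL_s_kg,perfusion_mL_s,delta_pct
head,core,1.18,1128,1331,9.21,12.97,91
head,muscle,0.38,,429,0.55,0.23,1.6
head,fat,0.3,,338,0.004,0,0
head,skin,0.17,,191,4.9,1.0,7.4
head,bone,0.17,,191,0,0,0
head,total,2.2,,2480,,14.2,100
torso,core,1.76,6016,10588,4.3,48,90
torso,muscle,1.18,,7110,0.51,3.81,7.1
torso,fat,0.7,,4211,0.004,0.018,0.03
torso,skin,0.12,,722,1.9,1.5,2.87
torso,bone,0.14,,842,0,0,0
torso,total,3.62,,23473,,53.328,100
upper_limbs,muscle,1.28,3180,4070,0.6,2.52,85.1
upper_limbs,fat,0.27,,858,0.004,0.003,0.1
upper_limbs,skin,0.1,,318,1.3,0.44,14.8
upper_limbs,bone,0.3,,870,0,0,0
upper_limbs,total,1.95,,6549,,2.963,100
lower_limbs,muscle,1.1,6392,7000,0.51,3.75,75.7
lower_limbs,fat,0.7,,4474,0.004,0.013,0.26
lower_limbs,skin,0.155,,990,1.0,1.1,24.04
lower_limbs,bone,0.5,,3196,0,0,0
lower_limbs,total,2.85,,15660,,4.95,100
hand,muscle,0.3,1000,300,0.25,0.14,17.5
hand,fat,0.15,,150,0.0075,0.0012,0.15
hand,skin,0.2,,200,3.3,0.66,82.35
hand,bone,1,,1000,0,0,0
hand,total,1.65,,1650,,0.8,100
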