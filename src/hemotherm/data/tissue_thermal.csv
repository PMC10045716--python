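segment,layer,lambda_W_mC,rho_kg_m3,c_J_kgC,r_cm2C_W,C_J_cm2C
head,core,0.53,1360,2450,222.64,3.93
head,bone,1.2,1300,1590,14.17,0.35
head,muscle,0.5,1050,3770,76,1.50
head,fat,0.21,850,2500,71.43,1.28
head,dermis,0.37,1200,3400,22.97,1.39
head,epidermis,0.26,1200,3600,3.08,0.035
torso,core,0.53,1360,2450,359.18,5.86
torso,bone,1.2,1300,1590,11.67,0.29
torso,muscle,0.5,1050,3770,236,4.67
torso,fat,0.21,850,2500,300,1.28
torso,dermis,0.37,1200,3400,32.43,0.49
torso,epidermis,0.26,1200,3600,3.08,0.035
upper_limbs,bone,1.16,1300,1590,86.21,2.07
upper_limbs,muscle,0.5,1050,3770,256,5.07
upper_limbs,fat,0.21,1000,3060,128.57,0.83
upper_limbs,dermis,0.37,1200,3400,45.95,0.69
upper_limbs,epidermis,0.26,1200,3600,3.08,0.035
lower_limbs,bone,1.16,1300,1590,86.21,2.07
lower_limbs,muscle,0.5,1050,3770,220,4.35
lower_limbs,fat,0.21,1000,3060,333.33,1.49
lower_limbs,dermis,0.37,1200,3400,41.89,0.63
lower_limbs,epidermis,0.26,1200,3600,3.08,0.035
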