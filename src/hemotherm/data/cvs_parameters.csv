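group,name,value,unit
preload,Ppu,7.4,mmHg
preload,Rpu,0.01,mmHg_s_mL
preload,Rpv,0.002,mmHg_s_mL
preload,Lmv,0.0005,mmHg_s2_mL
preload,Lpv,0.0005,mmHg_s2_mL
preload,Amv,4.0,cm2
aortic_trunk,Aav,4.0,cm2
aortic_trunk,Lao,0.0008,mmHg_s2_mL
aortic_trunk,Lav,0.0004,mmHg_s2_mL
aortic_trunk,Caa,0.1,mL_mmHg
aortic_trunk,Cda,0.1,mL_mmHg
aortic_trunk,Rao,0.04,mmHg_s_mL
aortic_trunk,Rta,0.02,mmHg_s_mL
head_artery,E0,0.6,mmHg_mL
head_artery,Z,15,mmHg_s_mL
head_artery,R,0.04,mmHg_s_mL
head_artery,L,0.002,mmHg_s2_mL
head_arteriole,C,0.2,mL_mmHg
head_arteriole,R,4.3,mmHg_s_mL
head_arteriole,L,0.003,mmHg_s2_mL
head_capillary,C,0.6,mL_mmHg
head_capillary,R,2.09,mmHg_s_mL
head_capillary,L,0.0005,mmHg_s2_mL
head_vein,C,2.3,mL_mmHg
head_vein,R,0.55,mmHg_s_mL
head_vein,L,0.0004,mmHg_s2_mL
upper_limbs_artery,E0,0.8,mmHg_mL
upper_limbs_artery,Z,13,mmHg_s_mL
upper_limbs_artery,R,0.1,mmHg_s_mL
upper_limbs_artery,L,0.003,mmHg_s2_mL
upper_limbs_arteriole,C,0.1,mL_mmHg
upper_limbs_arteriole,R,25.89,mmHg_s_mL
upper_limbs_arteriole,L,0.003,mmHg_s2_mL
upper_limbs_capillary,C,0.45,mL_mmHg
upper_limbs_capillary,R,4.18,mmHg_s_mL
upper_limbs_capillary,L,0.0005,mmHg_s2_mL
upper_limbs_vein,C,4.6,mL_mmHg
upper_limbs_vein,R,1.09,mmHg_s_mL
upper_limbs_vein,L,0.0004,mmHg_s2_mL
lumped,Rtor,1.94,mmHg_s_mL
lumped,Rllb,21.68,mmHg_s_mL
lumped,Rpr,1.4,mmHg_s_mL
lumped,Rpc,0.01,mmHg_s_mL
lumped,Cpc,2.0,mL_mmHg
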