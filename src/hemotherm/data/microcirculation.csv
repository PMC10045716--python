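segment,core_resistance_mmHg_s_mL,skin_resistance_mmHg_s_mL
head,4.7,62
torso,2,68
upper_limbs,30,189
lower_limbs,28,96
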