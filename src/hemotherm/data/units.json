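{
  "description": "Unit-system constants. The thermal network uses cm-based units (cm2.degC/W for areal resistance, J/cm2.degC for areal capacitance, temperatures in degC); the circulatory circuit uses mmHg, mL and s. All conversions between these and SI go through the factors below.",
  "PA_PER_MMHG": 133.322,
  "M3_PER_ML": 1e-06,
  "M2_PER_CM2": 0.0001,
  "M_PER_CM": 0.01,
  "CLO_M2C_PER_W": 0.155,
  "BLOOD_DENSITY_KG_M3": 1050.0,
  "BLOOD_SPECIFIC_HEAT_J_KGC": 3850.0
}
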