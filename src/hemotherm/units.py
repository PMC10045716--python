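"""Unit-system constants.

The tissue thermal network works in cm-based areal units exactly as the
property tables print them (areal resistance in cm²·°C/W, areal capacitance
in J/cm²·°C); the circulatory circuit works in mmHg / mL / s.  Every
conversion between those systems and SI goes through the constants defined
here, which are loaded from the machine-readable ``data/units.json`` so that
external tooling can read the same numbers.
"""

from __future__ import annotations

import json
from importlib import resources

with resources.files("hemotherm.data").joinpath("units.json").open() as _fh:
    _U = json.load(_fh)

#: Pa per mmHg.
PA_PER_MMHG: float = _U["PA_PER_MMHG"]
#: m³ per mL.
M3_PER_ML: float = _U["M3_PER_ML"]
#: m² per cm².
M2_PER_CM2: float = _U["M2_PER_CM2"]
#: m per cm.
M_PER_CM: float = _U["M_PER_CM"]
#: m²·°C/W per clo (clothing insulation unit).
CLO_M2C_PER_W: float = _U["CLO_M2C_PER_W"]
#: Default blood density, kg/m³ (standard literature value; configurable
#: wherever it enters a formula).
BLOOD_DENSITY: float = _U["BLOOD_DENSITY_KG_M3"]
#: Default blood specific heat, J/(kg·°C).
BLOOD_SPECIFIC_HEAT: float = _U["BLOOD_SPECIFIC_HEAT_J_KGC"]

#: Hydraulic resistance: Pa·s/m³ per (mmHg·s/mL).
RESISTANCE_SI_PER_MMHG_S_ML: float = PA_PER_MMHG / M3_PER_ML
#: Inertance: Pa·s²/m³ per (mmHg·s²/mL).
INERTANCE_SI_PER_MMHG_S2_ML: float = PA_PER_MMHG / M3_PER_ML
#: Compliance: m³/Pa per (mL/mmHg).
COMPLIANCE_SI_PER_ML_MMHG: float = M3_PER_ML / PA_PER_MMHG
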