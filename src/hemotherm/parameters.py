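"""Model constants derived from anatomy and tissue-property tables.

This module builds every derived constant the coupled model needs:

* vascular resistance / inertance / compliance from vessel anatomy
  (Poiseuille + thin-walled tube relations), converted to circuit units;
* blood-perfusion fractions δ_ij that partition a segment's arteriolar flow
  across its tissue layers, and the layer flows ω_ij = δ_ij·q_i;
* the perfusion thermal resistance R_Eq = 1/(qρc) coupling a tissue node to
  arterial blood temperature;
* thermal RC element values r = l/λ and C = cρl per tissue layer;
* surface heat exchange: total coefficient h_t = 1/(0.155·clo) + h_r + h_c
  and the environment resistance REL = 1/h_t.

The packaged tables (tissue thermal properties, layer perfusion,
microcirculation resistances, circuit parameters) are loaded here and
validated against their stated invariants on load.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from . import units

log = logging.getLogger(__name__)

SEGMENTS = ("head", "torso", "upper_limbs", "lower_limbs", "hand")
#: Layers carrying the "core" share of perfusion vs. the "skin" share.
#: Fat and dermis form the cutaneous group; everything perfused inside them
#: is core-side.  Bone is never perfused.
CORE_GROUP = ("core", "muscle")
SKIN_GROUP = ("fat", "skin")


# ---------------------------------------------------------------------------
# vascular RLC from anatomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselAnatomy:
    """Geometric and material description of a vessel segment (SI units).

    Parameters
    ----------
    mu : blood dynamic viscosity, Pa·s
    rho_b : blood density, kg/m³
    length : vessel length, m
    radius : inner radius, m
    E_wall : wall elastic modulus, Pa
    h_wall : wall thickness, m
    """

    mu: float
    rho_b: float
    length: float
    radius: float
    E_wall: float
    h_wall: float

    def __post_init__(self) -> None:
        for name in ("mu", "rho_b", "length", "radius", "E_wall", "h_wall"):
            if not getattr(self, name) > 0:
                raise ValueError(f"VesselAnatomy.{name} must be strictly positive")


@dataclass(frozen=True)
class VesselRLC:
    """Lumped circuit values of one vessel in mmHg / mL / s units."""

    R: float  # mmHg·s/mL
    L: float  # mmHg·s²/mL
    C: float  # mL/mmHg

    def __post_init__(self) -> None:
        if self.R < 0 or self.L < 0 or self.C < 0:
            raise ValueError("VesselRLC values must be non-negative")


def vessel_rlc(anatomy: VesselAnatomy) -> VesselRLC:
    """Poiseuille resistance, blood inertance and wall compliance of a vessel.

    R = 8μl/(πr⁴), L = ρl/(πr²), C = 3πr³l/(2Eh), evaluated in SI and
    converted to the circuit unit system (mmHg, mL, s).
    """
    a = anatomy
    r_si = 8.0 * a.mu * a.length / (math.pi * a.radius**4)
    l_si = a.rho_b * a.length / (math.pi * a.radius**2)
    c_si = 3.0 * math.pi * a.radius**3 * a.length / (2.0 * a.E_wall * a.h_wall)
    return VesselRLC(
        R=r_si / units.RESISTANCE_SI_PER_MMHG_S_ML,
        L=l_si / units.INERTANCE_SI_PER_MMHG_S2_ML,
        C=c_si / units.COMPLIANCE_SI_PER_ML_MMHG,
    )


# ---------------------------------------------------------------------------
# perfusion partitioning
# ---------------------------------------------------------------------------

@dataclass
class PerfusionTable:
    """Per-segment, per-layer geometry and blood perfusion.

    ``data`` has one row per (segment, layer) with columns ``l_cm``,
    ``A_cm2``, ``volume_cm3``, ``perfusion_mL_s`` and the printed reference
    percentage ``delta_pct``; ``totals`` holds the printed per-segment total
    rows used only for cross-checking.
    """

    data: pd.DataFrame
    totals: pd.DataFrame

    def segment(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["segment"] == name]
        if sub.empty:
            raise KeyError(f"unknown segment {name!r}")
        return sub

    def area(self, name: str) -> float:
        return float(self.segment(name)["A_cm2"].dropna().iloc[0])

    def perfusion(self, segment: str, layer: str) -> float:
        sub = self.segment(segment)
        row = sub[sub["layer"] == layer]
        if row.empty:
            raise KeyError(f"unknown layer {layer!r} in segment {segment!r}")
        return float(row["perfusion_mL_s"].iloc[0])


@dataclass(frozen=True)
class PerfusionFractions:
    """Dimensionless layer fractions δ_ij, summing to 1 within each segment."""

    delta: Mapping[tuple[str, str], float]

    def segment(self, name: str) -> dict[str, float]:
        out = {layer: f for (seg, layer), f in self.delta.items() if seg == name}
        if not out:
            raise KeyError(f"unknown segment {name!r}")
        return out


def perfusion_fractions(table: PerfusionTable) -> PerfusionFractions:
    """Compute δ_ij = BP_ij / Σ_j BP_ij per segment.

    The denominator is the recomputed sum over the segment's layers, not the
    printed total row (the two disagree by rounding in some segments).  Rows
    whose recomputed fraction deviates from the printed percentage by more
    than 0.5 points are logged, never silently corrected.
    """
    delta: dict[tuple[str, str], float] = {}
    for seg, sub in table.data.groupby("segment", sort=False):
        bp = sub["perfusion_mL_s"].astype(float)
        if (bp < 0).any():
            raise ValueError(f"negative perfusion in segment {seg!r}")
        total = bp.sum()
        if total <= 0:
            raise ValueError(f"segment {seg!r} has zero total perfusion")
        for _, row in sub.iterrows():
            frac = float(row["perfusion_mL_s"]) / total
            delta[(seg, row["layer"])] = frac
            printed = row.get("delta_pct")
            if printed is not None and not pd.isna(printed):
                if abs(100.0 * frac - float(printed)) > 0.5:
                    log.info(
                        "segment %s layer %s: recomputed fraction %.2f%% "
                        "differs from printed %.2f%%",
                        seg, row["layer"], 100.0 * frac, float(printed),
                    )
    return PerfusionFractions(delta=delta)


def distribute_perfusion(
    delta: PerfusionFractions, q_i: Mapping[str, float]
) -> dict[tuple[str, str], float]:
    """Layer flows ω_ij = δ_ij·q_i (mL/s) for each segment's arteriolar flow."""
    for seg, q in q_i.items():
        if q < 0:
            raise ValueError(f"negative arteriole flow for segment {seg!r}")
    omega = {}
    for (seg, layer), f in delta.delta.items():
        if seg in q_i:
            omega[(seg, layer)] = f * q_i[seg]
    return omega


def perfusion_thermal_resistance(
    q_mL_cm2_s: float,
    rho_b: float = units.BLOOD_DENSITY,
    c_b: float = units.BLOOD_SPECIFIC_HEAT,
) -> float:
    """Areal perfusion thermal resistance R_Eq = 1/(qρc), cm²·°C/W.

    ``q`` is blood perfusion per unit tissue area in mL/(cm²·s); a zero flow
    yields an infinite resistance (the blood source branch is open).
    """
    if q_mL_cm2_s < 0:
        raise ValueError("perfusion must be non-negative")
    if q_mL_cm2_s == 0:
        return math.inf
    q_si = q_mL_cm2_s * units.M3_PER_ML / units.M2_PER_CM2  # m³/(m²·s) = m/s
    r_si = 1.0 / (q_si * rho_b * c_b)  # m²·°C/W
    return r_si / units.M2_PER_CM2  # cm²·°C/W


def perfusion_source_resistance(
    omega_mL_s: float,
    rho_b: float = units.BLOOD_DENSITY,
    c_b: float = units.BLOOD_SPECIFIC_HEAT,
) -> float:
    """Absolute blood-source resistance 1/(ωρc) in °C/W for a layer flow ω (mL/s)."""
    if omega_mL_s < 0:
        raise ValueError("perfusion must be non-negative")
    if omega_mL_s == 0:
        return math.inf
    return 1.0 / (omega_mL_s * units.M3_PER_ML * rho_b * c_b)


# ---------------------------------------------------------------------------
# thermal RC elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerThermalProps:
    """Effective thermal properties and RC element values of one tissue layer.

    ``r_elem`` (cm²·°C/W) and ``C_elem`` (J/cm²·°C) are areal element values;
    they follow r = l/λ and C = cρl unless loaded verbatim from the property
    table (whose printed values are authoritative for default geometry).
    """

    name: str
    lambda_: float  # W/(m·°C)
    rho: float      # kg/m³
    c: float        # J/(kg·°C)
    l_cm: float     # cm
    r_elem: float   # cm²·°C/W
    C_elem: float   # J/(cm²·°C)


def layer_elements(lambda_: float, rho: float, c: float, l_cm: float) -> tuple[float, float]:
    """Areal element values (r, C) of a layer: r = l/λ, C = cρl.

    Returns ``r`` in cm²·°C/W and ``C`` in J/(cm²·°C) for thickness in cm and
    SI property values.
    """
    if lambda_ <= 0:
        raise ValueError("thermal conductivity must be positive")
    if rho <= 0 or c <= 0 or l_cm < 0:
        raise ValueError("layer properties must be positive, thickness non-negative")
    l_m = l_cm * units.M_PER_CM
    r_si = l_m / lambda_                      # m²·°C/W
    c_si = c * rho * l_m                      # J/(m²·°C)
    return r_si / units.M2_PER_CM2, c_si * units.M2_PER_CM2


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentSpec:
    """Ambient conditions and surface heat-exchange coefficients.

    h_t = 1/(0.155·clo) + h_r + h_c (W/m²·°C), taken as printed; ``clo`` may
    be ``inf`` for bare skin, in which limit h_t → h_r + h_c.  ``h_evap`` is
    an optional additive constant standing in for evaporative exchange
    (excluded by default; no governing equation is part of the model).
    ``re_factor`` sizes the parallel isolation-loss resistance
    Re = re_factor·REL, so a factor of 50 routes <2 % of the surface flux
    through the loss path.
    """

    Ta: float = 25.0          # °C
    clo: float = math.inf     # clothing insulation, clo units
    hr: float = 4.7           # radiative coefficient, W/(m²·°C)
    hc: float = 3.1           # convective coefficient, W/(m²·°C)
    h_evap: float = 0.0       # optional additive term, W/(m²·°C)
    re_factor: float = 50.0   # Re = re_factor × REL

    def __post_init__(self) -> None:
        if not self.clo > 0:
            raise ValueError("clo must be strictly positive (the 1/(0.155·clo) term diverges)")
        if self.re_factor <= 0:
            raise ValueError("re_factor must be positive")

    @property
    def ht(self) -> float:
        """Total heat transfer coefficient, W/(m²·°C)."""
        return total_heat_transfer_coeff(self)

    @property
    def REL_cm2(self) -> float:
        """Areal environment resistance 1/h_t in cm²·°C/W."""
        return 1.0 / (self.ht * units.M2_PER_CM2)

    @property
    def Re_cm2(self) -> float:
        """Areal isolation-loss resistance (parallel loss path), cm²·°C/W."""
        return self.re_factor * self.REL_cm2


def total_heat_transfer_coeff(env: EnvironmentSpec) -> float:
    """h_t = 1/(0.155·clo) + h_r + h_c in W/(m²·°C)."""
    if not env.clo > 0:
        raise ValueError("clo must be strictly positive")
    clothing = 0.0 if math.isinf(env.clo) else 1.0 / (units.CLO_M2C_PER_W * env.clo)
    ht = clothing + env.hr + env.hc + env.h_evap
    if ht <= 0:
        raise ValueError("total heat transfer coefficient must be positive")
    return ht


def env_heat_flux(ht: float, Tsk: float, Ta: float) -> float:
    """Surface heat flux Φ = h_t·(T_sk − T_a); ht in W/(cm²·°C) gives W/cm²."""
    return ht * (Tsk - Ta)


# ---------------------------------------------------------------------------
# microcirculation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrocirculationResistances:
    """Per-segment core and skin microcirculation resistances (mmHg·s/mL).

    ``parallel`` gives the combined arteriole-bed resistance; at the table
    defaults this reproduces the circuit table's printed single arteriole
    resistances (head 4.3, upper limbs 25.89, torso 1.94, lower limbs 21.68).
    """

    core: Mapping[str, float]
    skin: Mapping[str, float]

    def __post_init__(self) -> None:
        for d in (self.core, self.skin):
            for seg, v in d.items():
                if v <= 0:
                    raise ValueError(f"non-positive microcirculation resistance for {seg!r}")

    def parallel(self, segment: str) -> float:
        rc, rs = self.core[segment], self.skin[segment]
        return rc * rs / (rc + rs)


# Hand defaults: the resistance tables carry no hand row.  The skin value is
# the awake cohort mean; the core value is set so the hand's core/skin flow
# ratio matches its printed layer perfusion (0.14 vs 0.66 mL/s).
HAND_SKIN_RESISTANCE_DEFAULT = 114.4
HAND_CORE_RESISTANCE_DEFAULT = HAND_SKIN_RESISTANCE_DEFAULT * 0.66 / 0.14


# ---------------------------------------------------------------------------
# packaged table loaders
# ---------------------------------------------------------------------------

def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("hemotherm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_thermal_table() -> dict[tuple[str, str], LayerThermalProps]:
    """Tissue thermal properties with verbatim element values, keyed by (segment, layer)."""
    df = _read_csv("tissue_thermal.csv")
    out = {}
    thick = _read_csv("tissue_perfusion.csv").set_index(["segment", "layer"])["l_cm"]
    for _, row in df.iterrows():
        seg, layer = row["segment"], row["layer"]
        key = "skin" if layer in ("dermis", "epidermis") else layer
        l_cm = float(thick.get((seg, key), float("nan")))
        props = LayerThermalProps(
            name=layer,
            lambda_=float(row["lambda_W_mC"]),
            rho=float(row["rho_kg_m3"]),
            c=float(row["c_J_kgC"]),
            l_cm=l_cm,
            r_elem=float(row["r_cm2C_W"]),
            C_elem=float(row["C_J_cm2C"]),
        )
        if props.r_elem <= 0 or props.C_elem <= 0:
            raise ValueError(f"non-positive element value for {seg}/{layer}")
        out[(seg, layer)] = props
    return out


def load_perfusion_table() -> PerfusionTable:
    """Layer geometry and perfusion; validates non-negativity, zero bone flow and totals."""
    df = _read_csv("tissue_perfusion.csv")
    totals = df[df["layer"].str.lower() == "total"].copy()
    data = df[df["layer"].str.lower() != "total"].copy()
    if (data["perfusion_mL_s"] < 0).any():
        raise ValueError("negative layer perfusion in table")
    bone = data[data["layer"] == "bone"]
    if (bone["perfusion_mL_s"] != 0).any():
        raise ValueError("bone perfusion must be zero")
    for seg, sub in data.groupby("segment"):
        printed = float(totals[totals["segment"] == seg]["perfusion_mL_s"].iloc[0])
        recomputed = float(sub["perfusion_mL_s"].sum())
        if abs(recomputed - printed) > 0.1 + 0.02 * printed:
            raise ValueError(
                f"segment {seg!r}: layer perfusion sum {recomputed:.3f} "
                f"far from printed total {printed:.3f}"
            )
        if abs(recomputed - printed) > 1e-9:
            log.info(
                "segment %s: layer perfusion sum %.4f vs printed total %.4f (rounding)",
                seg, recomputed, printed,
            )
    return PerfusionTable(data=data.reset_index(drop=True), totals=totals.reset_index(drop=True))


def load_micro_resistances(
    hand_core: float = HAND_CORE_RESISTANCE_DEFAULT,
    hand_skin: float = HAND_SKIN_RESISTANCE_DEFAULT,
) -> MicrocirculationResistances:
    """Microcirculation resistances, with the derived hand defaults appended."""
    df = _read_csv("microcirculation.csv")
    core = dict(zip(df["segment"], df["core_resistance_mmHg_s_mL"].astype(float)))
    skin = dict(zip(df["segment"], df["skin_resistance_mmHg_s_mL"].astype(float)))
    core["hand"] = hand_core
    skin["hand"] = hand_skin
    return MicrocirculationResistances(core=core, skin=skin)


def load_cvs_table() -> dict[str, dict[str, float]]:
    """Circuit parameter table grouped as printed (preload / aortic trunk / branches / lumped)."""
    df = _read_csv("cvs_parameters.csv")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["group"], {})[row["name"]] = float(row["value"])
    return out
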