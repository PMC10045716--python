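"""Closed pulsatile 0D cardiovascular circuit.

The systemic circulation is an electrical-analog network: a constant
pulmonary perfusion pressure Ppu fills a pulmonary venous capacitance, which
feeds the left atrium and ventricle (time-varying elastance chambers joined
by smoothed orifice valves).  The arterial side carries an ascending/
descending aortic trunk with explicit cerebral and upper-limb branches
(artery → arteriole → capillary → vein compartments) and lumped torso,
lower-limb and peripheral beds.  Each perfused segment's microcirculation is
a parallel pair of core and skin resistances, so core blood flow (CBF) and
skin blood flow (SBF) are explicit branch currents; the hand bed taps the
upper-limb arteriole node.  All beds drain into a peripheral venous
capacitance that returns to the pulmonary source, closing the loop.

Units are mmHg / mL / s throughout.  The right-hand side is compiled with
numba and integrated with a fixed-step classical Runge–Kutta scheme; a run
advances whole cardiac cycles until the beat-to-beat pressure change at
every node falls below a tolerance (periodic steady state), then records one
final cycle on the output grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from numba import njit

from . import parameters, units

# --- state vector layout ---------------------------------------------------

STATE_NAMES = (
    "V_la", "V_lv", "P_pvc", "P_aa", "Q_ao", "P_da",
    "P_a_head", "Q_a_head", "P_al_head", "P_c_head", "P_v_head",
    "P_a_ulb", "Q_a_ulb", "P_al_ulb", "P_c_ulb", "P_v_ulb",
    "P_cpc", "Q_pv",
)
NSTATE = len(STATE_NAMES)
(IV_LA, IV_LV, IP_PVC, IP_AA, IQ_AO, IP_DA,
 IP_A_CER, IQ_A_CER, IP_AL_CER, IP_C_CER, IP_V_CER,
 IP_A_ULB, IQ_A_ULB, IP_AL_ULB, IP_C_ULB, IP_V_ULB,
 IP_CPC, IQ_PV) = range(NSTATE)

#: indices of pressure-like states used for the periodic-steady-state check
PRESSURE_STATES = (IP_PVC, IP_AA, IP_DA, IP_A_CER, IP_AL_CER, IP_C_CER,
                   IP_V_CER, IP_A_ULB, IP_AL_ULB, IP_C_ULB, IP_V_ULB, IP_CPC)

FLOW_NAMES = (
    "Q_mv", "Q_av", "Q_z_head", "Q_cv_head", "Q_vout_head",
    "Q_z_ulb", "Q_cv_ulb", "Q_vout_ulb",
    "Q_ta", "Q_tor", "Q_llb", "Q_pr", "Q_pc_ret", "Q_pu",
    "q_head_core", "q_head_skin", "q_upper_limbs_core", "q_upper_limbs_skin",
    "q_hand_core", "q_hand_skin", "q_torso_core", "q_torso_skin",
    "q_lower_limbs_core", "q_lower_limbs_skin",
    "P_la", "P_lv", "P_junction",
)
NFLOW = len(FLOW_NAMES)

# --- parameter vector layout ----------------------------------------------

_PAR_NAMES = (
    "Ppu", "Rpu", "Rpv", "Lpv", "Amv", "Aav", "Lao", "Caa", "Cda", "Rao", "Rta",
    "Ca_cer", "Z_cer", "Ra_cer", "La_cer", "Cal_cer", "Cc_cer", "Rc_cer", "Cv_cer", "Rv_cer",
    "Ca_ulb", "Z_ulb", "Ra_ulb", "La_ulb", "Cal_ulb", "Cc_ulb", "Rc_ulb", "Cv_ulb", "Rv_ulb",
    "Rcore_head", "Rskin_head", "Rcore_ulb", "Rskin_ulb", "Rcore_hand", "Rskin_hand",
    "Rcore_tor", "Rskin_tor", "Rcore_llb", "Rskin_llb",
    "Rpr", "Rpc", "Cpc", "Cpvc",
    "HR", "Emax_lv", "Emin_lv", "V0_lv", "Emax_la", "Emin_la", "V0_la",
    "t_sys", "K_valve", "eps_valve", "v_scale", "v_norm", "la_onset", "la_scale",
    "la_norm", "valve_lin_r",
)
_PI = {n: i for i, n in enumerate(_PAR_NAMES)}
NPAR = len(_PAR_NAMES)

_HILL_A1, _HILL_A2, _HILL_N1, _HILL_N2 = 0.303, 0.508, 1.9, 21.9


def _hill_shape(x: np.ndarray, scale: float) -> np.ndarray:
    """Un-normalised double-Hill activation, phase x in [0, 1)."""
    xa = x / (_HILL_A1 * scale)
    xb = x / (_HILL_A2 * scale)
    h1 = xa**_HILL_N1
    return h1 / (1.0 + h1) / (1.0 + xb**_HILL_N2)


def _hill_calibration(t_sys_frac: float) -> tuple[float, float]:
    """Time scale and normalisation so the peak sits at phase t_sys_frac with height 1."""
    x = np.linspace(1e-6, 1.0, 20001)
    base = _hill_shape(x, 1.0)
    m0 = x[int(np.argmax(base))]
    scale = t_sys_frac / m0
    peak = float(np.max(_hill_shape(x, scale)))
    return scale, 1.0 / peak


# --- compiled kernel -------------------------------------------------------

@njit(cache=True)
def _shape_nb(x, scale, norm):
    xa = x / (0.303 * scale)
    xb = x / (0.508 * scale)
    h1 = xa**1.9
    return norm * h1 / (1.0 + h1) / (1.0 + xb**21.9)


@njit(cache=True)
def _qvalve_nb(dp, A, K, eps, rlin):
    # softplus ramp on the forward pressure: smooth (C-infinity) opening over
    # ~eps mmHg, exponentially tight closure under reverse pressure
    if rlin > 0.0:
        return dp / rlin
    if dp > 0.0:
        dpe = dp + eps * math.log1p(math.exp(-dp / eps))
    else:
        dpe = eps * math.log1p(math.exp(dp / eps))
    return A * math.sqrt(dpe / K)


@njit(cache=True)
def _eval_nb(y, x, p, dy, fl):
    """Fill dy (state derivatives) and fl (instantaneous flows/pressures) at phase x."""
    Elv = p[45] + (p[44] - p[45]) * _shape_nb(x, p[53], p[54])
    xla = x - p[55]
    if xla < 0.0:
        xla += 1.0
    Ela = p[48] + (p[47] - p[48]) * _shape_nb(xla, p[56], p[57])
    P_la = Ela * (y[0] - p[49])
    P_lv = Elv * (y[1] - p[46])

    Q_pu = (p[0] - y[2]) / p[1]
    Q_mv = _qvalve_nb(P_la - P_lv, p[4], p[51], p[52], p[58])
    Q_av = _qvalve_nb(P_lv - y[3], p[5], p[51], p[52], p[58])

    dy[17] = (y[2] - P_la - p[2] * y[17]) / p[3]      # pulmonary venous inflow
    dy[0] = y[17] - Q_mv
    dy[1] = Q_mv - Q_av

    # cerebral branch
    Qz_c = (y[3] - y[6]) / p[12]
    dy[6] = (Qz_c - y[7]) / p[11]
    dy[7] = (y[6] - y[8] - p[13] * y[7]) / p[14]
    dpm = y[8] - y[9]
    qhc = dpm / p[29]
    qhs = dpm / p[30]
    dy[8] = (y[7] - qhc - qhs) / p[15]
    Qcv_c = (y[9] - y[10]) / p[17]
    dy[9] = (qhc + qhs - Qcv_c) / p[16]
    Qv_c = (y[10] - y[16]) / p[19]
    dy[10] = (Qcv_c - Qv_c) / p[18]

    # upper-limb branch with hand bed on the arteriole node
    Qz_u = (y[3] - y[11]) / p[21]
    dy[11] = (Qz_u - y[12]) / p[20]
    dy[12] = (y[11] - y[13] - p[22] * y[12]) / p[23]
    dpu = y[13] - y[14]
    quc = dpu / p[31]
    qus = dpu / p[32]
    qnc = dpu / p[33]
    qns = dpu / p[34]
    dy[13] = (y[12] - quc - qus - qnc - qns) / p[24]
    Qcv_u = (y[14] - y[15]) / p[26]
    dy[14] = (quc + qus + qnc + qns - Qcv_u) / p[25]
    Qv_u = (y[15] - y[16]) / p[28]
    dy[15] = (Qcv_u - Qv_u) / p[27]

    # aortic trunk
    dy[3] = (Q_av - Qz_c - Qz_u - y[4]) / p[7]
    dy[4] = (y[3] - y[5] - p[9] * y[4]) / p[6]

    # descending junction (purely resistive node, solved algebraically)
    Gtor = 1.0 / p[35] + 1.0 / p[36]
    Gllb = 1.0 / p[37] + 1.0 / p[38]
    Gout = Gtor + Gllb + 1.0 / p[39]
    GJ = 1.0 / p[10] + Gout
    PJ = (y[5] / p[10] + Gout * y[16]) / GJ
    Qta = (y[5] - PJ) / p[10]
    dy[5] = (y[4] - Qta) / p[8]
    dpj = PJ - y[16]
    qtc = dpj / p[35]
    qts = dpj / p[36]
    qlc = dpj / p[37]
    qls = dpj / p[38]
    Qpr = dpj / p[39]
    Qpc = (y[16] - y[2]) / p[40]
    dy[16] = (Qv_c + Qv_u + qtc + qts + qlc + qls + Qpr - Qpc) / p[41]
    dy[2] = (Q_pu + Qpc - y[17]) / p[42]

    fl[0] = Q_mv
    fl[1] = Q_av
    fl[2] = Qz_c
    fl[3] = Qcv_c
    fl[4] = Qv_c
    fl[5] = Qz_u
    fl[6] = Qcv_u
    fl[7] = Qv_u
    fl[8] = Qta
    fl[9] = qtc + qts
    fl[10] = qlc + qls
    fl[11] = Qpr
    fl[12] = Qpc
    fl[13] = Q_pu
    fl[14] = qhc
    fl[15] = qhs
    fl[16] = quc
    fl[17] = qus
    fl[18] = qnc
    fl[19] = qns
    fl[20] = qtc
    fl[21] = qts
    fl[22] = qlc
    fl[23] = qls
    fl[24] = P_la
    fl[25] = P_lv
    fl[26] = PJ


@njit(cache=True)
def _run_cycles_nb(y, p, dt, n_max, tol, press_idx):
    """Advance whole cycles by RK4 until the beat-to-beat pressure change < tol.

    Returns (n_cycles, residual, ok) with ok=0 on convergence, 1 when the
    cycle budget is exhausted, 2 on a non-finite state.
    """
    T = 60.0 / p[43]
    n_steps = int(round(T / dt))
    h = T / n_steps
    k1 = np.empty(18)
    k2 = np.empty(18)
    k3 = np.empty(18)
    k4 = np.empty(18)
    yt = np.empty(18)
    fl = np.empty(27)
    y_prev = y.copy()
    resid = math.inf
    for cyc in range(n_max):
        for i in range(n_steps):
            x = i / n_steps
            xh = (i + 0.5) / n_steps
            x1 = ((i + 1) % n_steps) / n_steps
            _eval_nb(y, x, p, k1, fl)
            for j in range(18):
                yt[j] = y[j] + 0.5 * h * k1[j]
            _eval_nb(yt, xh, p, k2, fl)
            for j in range(18):
                yt[j] = y[j] + 0.5 * h * k2[j]
            _eval_nb(yt, xh, p, k3, fl)
            for j in range(18):
                yt[j] = y[j] + h * k3[j]
            _eval_nb(yt, x1, p, k4, fl)
            for j in range(18):
                y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        resid = 0.0
        for j in press_idx:
            d = abs(y[j] - y_prev[j])
            if d > resid:
                resid = d
        for j in range(18):
            if not math.isfinite(y[j]):
                return cyc + 1, resid, 2
        if resid < tol:
            return cyc + 1, resid, 0
        for j in range(18):
            y_prev[j] = y[j]
    return n_max, resid, 1


@njit(cache=True)
def _record_cycle_nb(y, p, dt):
    """Integrate one cycle, recording states and flows on the fixed output grid."""
    T = 60.0 / p[43]
    n_steps = int(round(T / dt))
    h = T / n_steps
    states = np.empty((n_steps + 1, 18))
    flows = np.empty((n_steps + 1, 27))
    k1 = np.empty(18)
    k2 = np.empty(18)
    k3 = np.empty(18)
    k4 = np.empty(18)
    yt = np.empty(18)
    fl = np.empty(27)
    for i in range(n_steps):
        x = i / n_steps
        xh = (i + 0.5) / n_steps
        x1 = ((i + 1) % n_steps) / n_steps
        _eval_nb(y, x, p, k1, fl)
        states[i, :] = y
        flows[i, :] = fl
        for j in range(18):
            yt[j] = y[j] + 0.5 * h * k1[j]
        _eval_nb(yt, xh, p, k2, fl)
        for j in range(18):
            yt[j] = y[j] + 0.5 * h * k2[j]
        _eval_nb(yt, xh, p, k3, fl)
        for j in range(18):
            yt[j] = y[j] + h * k3[j]
        _eval_nb(yt, x1, p, k4, fl)
        for j in range(18):
            y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    _eval_nb(y, 0.0, p, k1, fl)
    states[n_steps, :] = y
    flows[n_steps, :] = fl
    return states, flows, h


# --- parameter containers --------------------------------------------------

@dataclass(frozen=True)
class HeartParams:
    """Preload source, valves and time-varying elastance chambers.

    The elastance bounds, unstressed volumes and systolic timing are not
    tabulated model inputs; the defaults follow standard 0D practice with the
    ventricular bounds calibrated once so mean aortic pressure at the resting
    heart rate (76.6 bpm) lands near 106.6 mmHg.
    """

    Ppu: float = 7.4        # pulmonary perfusion pressure, mmHg
    Rpu: float = 0.01
    Rpv: float = 0.002
    Lpv: float = 0.0005
    Lmv: float = 0.0005     # retained for completeness; valves are instantaneous orifices
    Amv: float = 4.0        # cm²
    Aav: float = 4.0        # cm²
    HR: float = 76.6        # beats/min
    Emax_lv: float = 5.0    # mmHg/mL (calibrated, see docs/methods.md)
    Emin_lv: float = 0.05
    Emax_la: float = 0.25
    Emin_la: float = 0.15
    V0_lv: float = 10.0     # mL
    V0_la: float = 4.0
    t_sys_frac: float = 0.3
    la_onset_frac: float = 0.82
    la_sys_frac: float = 0.12

    def __post_init__(self) -> None:
        if not (self.Emax_lv >= self.Emin_lv > 0 and self.Emax_la >= self.Emin_la > 0):
            raise ValueError("elastance bounds must satisfy Emax >= Emin > 0")
        if not 0 < self.t_sys_frac < 1:
            raise ValueError("t_sys_frac must lie in (0, 1)")
        if self.HR <= 0:
            raise ValueError("heart rate must be positive")


@dataclass(frozen=True)
class Vessel:
    """One vascular compartment: compliance with downstream resistance/inertance."""
    C: float
    R: float
    L: float = 0.0


@dataclass(frozen=True)
class Branch:
    """Artery→arteriole→capillary→vein chain of one explicit circulation branch.

    The artery column "E0:Z:R:L" is realised as a compliance 1/E0 fed through
    the characteristic impedance Z, ahead of the R–L segment.
    """
    E0: float
    Z: float
    Ra: float
    La: float
    arteriole: Vessel
    capillary: Vessel
    vein: Vessel


@dataclass(frozen=True)
class BranchParams:
    """Everything outside the heart: trunk, branches, lumped beds, microcirculation."""

    Lao: float = 0.0008
    Lav: float = 0.0004
    Caa: float = 0.1
    Cda: float = 0.1
    Rao: float = 0.04
    Rta: float = 0.02
    head: Branch = field(default_factory=lambda: Branch(
        E0=0.6, Z=15.0, Ra=0.04, La=0.002,
        arteriole=Vessel(C=0.2, R=4.3, L=0.003),
        capillary=Vessel(C=0.6, R=2.09, L=0.0005),
        vein=Vessel(C=2.3, R=0.55, L=0.0004)))
    upper_limbs: Branch = field(default_factory=lambda: Branch(
        E0=0.8, Z=13.0, Ra=0.1, La=0.003,
        arteriole=Vessel(C=0.1, R=25.89, L=0.003),
        capillary=Vessel(C=0.45, R=4.18, L=0.0005),
        vein=Vessel(C=4.6, R=1.09, L=0.0004)))
    Rpr: float = 1.4
    Rpc: float = 0.01
    Cpc: float = 2.0
    Cpvc: float = 10.0      # pulmonary venous pool; pressure-pinned by the source


@dataclass(frozen=True)
class CVSParameters:
    """Full circuit parameter set, including microcirculation resistances."""

    heart: HeartParams = field(default_factory=HeartParams)
    branches: BranchParams = field(default_factory=BranchParams)
    micro: parameters.MicrocirculationResistances = field(
        default_factory=parameters.load_micro_resistances)
    rho_b: float = units.BLOOD_DENSITY
    eps_valve: float = 0.02     # mmHg, smoothing band of the orifice law
    valve_linear_r: float = 0.0  # >0 replaces the orifice by a linear resistance

    @classmethod
    def default(cls) -> "CVSParameters":
        return cls()

    def with_updates(self, *, HR: float | None = None,
                     R_skin: Mapping[str, float] | None = None,
                     **heart_kw) -> "CVSParameters":
        """New parameter set with heart rate and/or skin resistances replaced."""
        heart = self.heart
        if HR is not None:
            heart_kw["HR"] = HR
        if heart_kw:
            heart = replace(heart, **heart_kw)
        micro = self.micro
        if R_skin:
            skin = dict(micro.skin)
            for seg, v in R_skin.items():
                if seg not in skin:
                    raise KeyError(f"unknown segment {seg!r}")
                skin[seg] = float(v)
            micro = parameters.MicrocirculationResistances(core=dict(micro.core), skin=skin)
        return replace(self, heart=heart, micro=micro)

    def pack(self) -> np.ndarray:
        h, b, m = self.heart, self.branches, self.micro
        v_scale, v_norm = _hill_calibration(h.t_sys_frac)
        la_scale, la_norm = _hill_calibration(h.la_sys_frac)
        k_valve = self.rho_b * units.M2_PER_CM2 / (2.0 * units.PA_PER_MMHG)
        vals = {
            "Ppu": h.Ppu, "Rpu": h.Rpu, "Rpv": h.Rpv, "Lpv": h.Lpv,
            "Amv": h.Amv, "Aav": h.Aav,
            "Lao": b.Lao, "Caa": b.Caa, "Cda": b.Cda, "Rao": b.Rao, "Rta": b.Rta,
            "Ca_cer": 1.0 / b.head.E0, "Z_cer": b.head.Z, "Ra_cer": b.head.Ra,
            "La_cer": b.head.La, "Cal_cer": b.head.arteriole.C,
            "Cc_cer": b.head.capillary.C, "Rc_cer": b.head.capillary.R,
            "Cv_cer": b.head.vein.C, "Rv_cer": b.head.vein.R,
            "Ca_ulb": 1.0 / b.upper_limbs.E0, "Z_ulb": b.upper_limbs.Z,
            "Ra_ulb": b.upper_limbs.Ra, "La_ulb": b.upper_limbs.La,
            "Cal_ulb": b.upper_limbs.arteriole.C,
            "Cc_ulb": b.upper_limbs.capillary.C, "Rc_ulb": b.upper_limbs.capillary.R,
            "Cv_ulb": b.upper_limbs.vein.C, "Rv_ulb": b.upper_limbs.vein.R,
            "Rcore_head": m.core["head"], "Rskin_head": m.skin["head"],
            "Rcore_ulb": m.core["upper_limbs"], "Rskin_ulb": m.skin["upper_limbs"],
            "Rcore_hand": m.core["hand"], "Rskin_hand": m.skin["hand"],
            "Rcore_tor": m.core["torso"], "Rskin_tor": m.skin["torso"],
            "Rcore_llb": m.core["lower_limbs"], "Rskin_llb": m.skin["lower_limbs"],
            "Rpr": b.Rpr, "Rpc": b.Rpc, "Cpc": b.Cpc, "Cpvc": b.Cpvc,
            "HR": h.HR, "Emax_lv": h.Emax_lv, "Emin_lv": h.Emin_lv, "V0_lv": h.V0_lv,
            "Emax_la": h.Emax_la, "Emin_la": h.Emin_la, "V0_la": h.V0_la,
            "t_sys": h.t_sys_frac, "K_valve": k_valve, "eps_valve": self.eps_valve,
            "v_scale": v_scale, "v_norm": v_norm,
            "la_onset": h.la_onset_frac, "la_scale": la_scale, "la_norm": la_norm,
            "valve_lin_r": self.valve_linear_r,
        }
        p = np.zeros(NPAR)
        for name, v in vals.items():
            p[_PI[name]] = v
        return p


# --- public operations ------------------------------------------------------

def elastance(t: float | np.ndarray, HR: float, heart: HeartParams,
              chamber: str = "lv") -> float | np.ndarray:
    """Chamber elastance E(t) in mmHg/mL; periodic with period 60/HR."""
    T = 60.0 / HR
    x = np.mod(np.asarray(t, dtype=float), T) / T
    if chamber == "lv":
        scale, norm = _hill_calibration(heart.t_sys_frac)
        emin, emax = heart.Emin_lv, heart.Emax_lv
    elif chamber == "la":
        scale, norm = _hill_calibration(heart.la_sys_frac)
        emin, emax = heart.Emin_la, heart.Emax_la
        x = np.mod(x - heart.la_onset_frac, 1.0)
    else:
        raise ValueError(f"unknown chamber {chamber!r}")
    e = emin + (emax - emin) * norm * _hill_shape(np.maximum(x, 1e-12), scale)
    return float(e) if np.isscalar(t) else e


def valve_flow(dP: float, A: float, rho_b: float = units.BLOOD_DENSITY,
               eps: float = 0.02) -> float:
    """Unidirectional orifice flow (mL/s) through a valve of area A (cm²).

    Forward flow follows the Bernoulli orifice law ΔP = K·Q|Q|/A² with
    K = ρ_b/2 in circuit units; the opening is smoothed over ``eps`` mmHg so
    Q is continuous (and ≈0 for reverse pressure).
    """
    if A <= 0:
        raise ValueError("valve area must be positive")
    K = rho_b * units.M2_PER_CM2 / (2.0 * units.PA_PER_MMHG)
    return float(_qvalve_nb(dP, A, K, eps, 0.0))


class CirculationError(RuntimeError):
    pass


def cvs_rhs(state: np.ndarray, t: float, params: CVSParameters | np.ndarray) -> np.ndarray:
    """Time derivative of the circuit state (see STATE_NAMES for the layout)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (NSTATE,):
        raise ValueError(f"state must have length {NSTATE}")
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise CirculationError(f"non-finite state at node {STATE_NAMES[bad[0]]}")
    p = params.pack() if isinstance(params, CVSParameters) else np.asarray(params)
    T = 60.0 / p[_PI["HR"]]
    x = (t % T) / T
    dy = np.empty(NSTATE)
    fl = np.empty(NFLOW)
    _eval_nb(y, x, p, dy, fl)
    return dy


def instantaneous_flows(state: np.ndarray, t: float,
                        params: CVSParameters | np.ndarray) -> dict[str, float]:
    """All branch flows and auxiliary pressures at one instant, keyed by FLOW_NAMES."""
    y = np.asarray(state, dtype=float)
    p = params.pack() if isinstance(params, CVSParameters) else np.asarray(params)
    T = 60.0 / p[_PI["HR"]]
    x = (t % T) / T
    dy = np.empty(NSTATE)
    fl = np.empty(NFLOW)
    _eval_nb(y, x, p, dy, fl)
    return dict(zip(FLOW_NAMES, fl))


@dataclass
class HemoSeries:
    """One recorded cardiac cycle on a uniform time grid."""

    t: np.ndarray                 # s, length n+1
    states: np.ndarray            # (n+1, NSTATE)
    flows: np.ndarray             # (n+1, NFLOW)
    period: float                 # s

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def flow(self, name: str) -> np.ndarray:
        return self.flows[:, FLOW_NAMES.index(name)]

    @property
    def aortic_pressure(self) -> np.ndarray:
        return self.state("P_aa")

    @property
    def aortic_flow(self) -> np.ndarray:
        return self.flow("Q_av")


@dataclass
class SimulationResult:
    series: HemoSeries
    final_state: np.ndarray
    converged: bool
    n_cycles: int
    residual: float               # mmHg, worst beat-to-beat node change
    summary: dict[str, float]


def default_initial_state(params: CVSParameters) -> np.ndarray:
    """Reproducible startup: 10 mmHg everywhere, chambers at V0 + 50 mL, no inductor flow."""
    y = np.full(NSTATE, 10.0)
    y[IV_LA] = params.heart.V0_la + 50.0
    y[IV_LV] = params.heart.V0_lv + 50.0
    y[IQ_AO] = 0.0
    y[IQ_A_CER] = 0.0
    y[IQ_A_ULB] = 0.0
    y[IQ_PV] = 0.0
    return y


def cycle_average_flows(series: HemoSeries) -> dict[str, float]:
    """Cycle-averaged microcirculation inflow q_i (mL/s) per body segment."""
    span = series.t[-1] - series.t[0]
    if span < series.period * (1.0 - 1e-9):
        raise ValueError("series shorter than one cardiac cycle")
    out = {}
    for seg in parameters.SEGMENTS:
        q = series.flow(f"q_{seg}_core") + series.flow(f"q_{seg}_skin")
        out[seg] = float(np.trapezoid(q, series.t) / span)
    return out


def cycle_average_sbf_cbf(series: HemoSeries) -> tuple[dict[str, float], dict[str, float]]:
    """Cycle-averaged skin and core blood flow (mL/s) per segment."""
    span = series.t[-1] - series.t[0]
    sbf = {seg: float(np.trapezoid(series.flow(f"q_{seg}_skin"), series.t) / span)
           for seg in parameters.SEGMENTS}
    cbf = {seg: float(np.trapezoid(series.flow(f"q_{seg}_core"), series.t) / span)
           for seg in parameters.SEGMENTS}
    return sbf, cbf


def simulate_cvs(params: CVSParameters, n_max_cycles: int = 120, dt: float = 1e-4,
                 tol_pss: float = 0.1, y0: np.ndarray | None = None,
                 strict: bool = True) -> SimulationResult:
    """Integrate the circuit to periodic steady state and record the final cycle.

    Convergence means the beat-to-beat absolute pressure change at every
    capacitive node falls below ``tol_pss`` (mmHg).  ``y0`` permits warm
    starts from a previous solution; ``dt`` is the fixed integration and
    output step (must be ≤ 1 ms).
    """
    if dt > 1e-3 or dt <= 0:
        raise ValueError("dt must be positive and at most 1 ms")
    p = params.pack()
    y = default_initial_state(params) if y0 is None else np.array(y0, dtype=float)
    press = np.array(PRESSURE_STATES, dtype=np.int64)
    n_cyc, resid, code = _run_cycles_nb(y, p, dt, n_max_cycles, tol_pss, press)
    if code == 2:
        raise CirculationError("state became non-finite during integration")
    if code == 1 and strict:
        raise CirculationError(
            f"no periodic steady state within {n_max_cycles} cycles "
            f"(worst node residual {resid:.3g} mmHg)")
    states, flows, h = _record_cycle_nb(y.copy(), p, dt)
    t = np.arange(states.shape[0]) * h
    series = HemoSeries(t=t, states=states, flows=flows, period=60.0 / params.heart.HR)
    q_i = cycle_average_flows(series)
    sbf, cbf = cycle_average_sbf_cbf(series)
    span = t[-1] - t[0]
    summary = {
        "MAP_mmHg": float(np.trapezoid(series.aortic_pressure, t) / span),
        "P_ao_systolic_mmHg": float(series.aortic_pressure.max()),
        "P_ao_diastolic_mmHg": float(series.aortic_pressure.min()),
        "Q_ao_mean_mL_s": float(np.trapezoid(series.aortic_flow, t) / span),
        "Q_ao_peak_mL_s": float(series.aortic_flow.max()),
        "HR_bpm": params.heart.HR,
    }
    for seg in parameters.SEGMENTS:
        summary[f"q_{seg}_mL_s"] = q_i[seg]
        summary[f"SBF_{seg}_mL_s"] = sbf[seg]
        summary[f"CBF_{seg}_mL_s"] = cbf[seg]
    return SimulationResult(series=series, final_state=y, converged=(code == 0),
                            n_cycles=n_cyc, residual=resid, summary=summary)


def conservation_check(result: SimulationResult, params: CVSParameters) -> dict[str, float]:
    """Volume drift per cycle over throughput for every capacitive compartment."""
    s = result.series
    t = s.t
    b = params.branches
    drift = {}

    def frac(dvol: float, q_in: np.ndarray) -> float:
        thr = np.trapezoid(np.maximum(q_in, 0.0), t)
        return abs(dvol) / max(thr, 1e-12)

    drift["la"] = frac(s.state("V_la")[-1] - s.state("V_la")[0], s.flow("Q_mv"))
    drift["lv"] = frac(s.state("V_lv")[-1] - s.state("V_lv")[0], s.flow("Q_av"))
    for name, C, qin in [
        ("P_aa", b.Caa, s.flow("Q_av")),
        ("P_da", b.Cda, s.state("Q_ao")),
        ("P_a_head", 1.0 / b.head.E0, s.flow("Q_z_head")),
        ("P_al_head", b.head.arteriole.C, s.state("Q_a_head")),
        ("P_c_head", b.head.capillary.C,
         s.flow("q_head_core") + s.flow("q_head_skin")),
        ("P_v_head", b.head.vein.C, s.flow("Q_cv_head")),
        ("P_a_ulb", 1.0 / b.upper_limbs.E0, s.flow("Q_z_ulb")),
        ("P_al_ulb", b.upper_limbs.arteriole.C, s.state("Q_a_ulb")),
        ("P_c_ulb", b.upper_limbs.capillary.C,
         s.flow("q_upper_limbs_core") + s.flow("q_upper_limbs_skin")
         + s.flow("q_hand_core") + s.flow("q_hand_skin")),
        ("P_v_ulb", b.upper_limbs.vein.C, s.flow("Q_cv_ulb")),
        ("P_cpc", b.Cpc,
         s.flow("Q_vout_head") + s.flow("Q_vout_ulb") + s.flow("Q_tor")
         + s.flow("Q_llb") + s.flow("Q_pr")),
        ("P_pvc", b.Cpvc, s.flow("Q_pu") + s.flow("Q_pc_ret")),
    ]:
        dvol = C * (s.state(name)[-1] - s.state(name)[0])
        drift[name] = frac(dvol, qin)
    return drift
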