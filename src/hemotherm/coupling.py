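"""Coupling of the pulsatile circulation to the tissue thermal networks.

One coupling pass runs the circuit to periodic steady state, takes the
cycle-averaged microcirculation flows per segment, splits them into
per-layer perfusions, and solves each segment's thermal network at steady
state.  Skin-group layers (fat, dermis) share the segment's skin blood flow
and core-group layers its core blood flow, weighted by the layer perfusion
fractions renormalised within each group — at the default resistances this
reproduces the plain δ_ij·q_i distribution exactly, and it keeps the
skin-resistance → skin-temperature mechanism intact when resistances are
perturbed away from the defaults.

With arterial-temperature feedback enabled the blood temperature is updated
from the perfusion-weighted venous return and the pass repeats until the
skin temperatures settle; without it (the default) a single pass is the
fixed point by construction, since nothing feeds back from tissue to the
circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circulation, parameters, thermal

#: thermal-layer membership of the skin vs. core perfusion groups
_SKIN_LAYERS = ("fat", "dermis")
_CORE_LAYERS = ("core", "muscle")
#: perfusion-table key for each thermal layer
_DELTA_KEY = {"core": "core", "muscle": "muscle", "fat": "fat", "dermis": "skin"}


@dataclass
class IntegratedConfig:
    """Settings of the coupling loop."""

    tol_T: float = 0.01           # °C, skin-temperature convergence tolerance
    max_iter: int = 20
    feedback_Tb: bool = False     # update arterial temperature from venous return
    T_b: float = 37.0             # arterial blood temperature, °C
    dt: float = 1e-4              # s, circuit integration step
    tol_pss: float = 0.1          # mmHg, periodic-steady-state tolerance
    n_max_cycles: int = 120
    segments: tuple[str, ...] = parameters.SEGMENTS

    def __post_init__(self) -> None:
        if self.tol_T <= 0:
            raise ValueError("tol_T must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class IntegratedResult:
    converged: bool
    iterations: int
    fields: dict[str, thermal.TemperatureField]
    series: circulation.HemoSeries
    omega: dict[tuple[str, str], float]       # (segment, thermal layer) → mL/s
    summary: dict[str, float]
    trace: list[dict[str, float]] = field(default_factory=list)
    final_state: np.ndarray | None = None
    T_b: float = 37.0

    @property
    def skin_temperatures(self) -> dict[str, float]:
        return {seg: f.skin for seg, f in self.fields.items()}


def layer_perfusion(segment: str, delta: parameters.PerfusionFractions,
                    cbf: float, sbf: float) -> dict[str, float]:
    """Per-layer flows (mL/s): CBF over the core group, SBF over the skin
    group, δ-weighted within each group."""
    d = delta.segment(segment)
    omega: dict[str, float] = {}
    for group, flow in ((_CORE_LAYERS, cbf), (_SKIN_LAYERS, sbf)):
        keys = [lay for lay in group if _DELTA_KEY[lay] in d]
        wsum = sum(d[_DELTA_KEY[lay]] for lay in keys)
        for lay in keys:
            if wsum > 0:
                omega[lay] = flow * d[_DELTA_KEY[lay]] / wsum
            else:
                # degenerate table row: give the whole group flow to its main layer
                omega[lay] = flow if lay in ("dermis", "muscle") else 0.0
    return omega


class IntegratedModel:
    """Forward model: circuit parameters + segment specs → temperatures and flows."""

    def __init__(self, cvs_params: circulation.CVSParameters | None = None,
                 segment_specs: dict[str, thermal.SegmentSpec] | None = None,
                 delta: parameters.PerfusionFractions | None = None,
                 config: IntegratedConfig | None = None):
        self.cvs_params = cvs_params or circulation.CVSParameters.default()
        self.config = config or IntegratedConfig()
        self.delta = delta or parameters.perfusion_fractions(parameters.load_perfusion_table())
        if segment_specs is None:
            segment_specs = {seg: thermal.default_segment_spec(seg)
                             for seg in self.config.segments}
        self.segment_specs = segment_specs

    def run(self, y0: np.ndarray | None = None) -> IntegratedResult:
        cfg = self.config
        T_b = cfg.T_b
        prev_tsk: dict[str, float] = {}
        trace: list[dict[str, float]] = []
        converged = False
        n_pass = cfg.max_iter if cfg.feedback_Tb else 1
        sim = None
        for it in range(1, n_pass + 1):
            if sim is None:  # the circuit does not depend on T_b; solve it once
                sim = circulation.simulate_cvs(
                    self.cvs_params, n_max_cycles=cfg.n_max_cycles,
                    dt=cfg.dt, tol_pss=cfg.tol_pss, y0=y0, strict=False)
            fields: dict[str, thermal.TemperatureField] = {}
            omega: dict[tuple[str, str], float] = {}
            for seg, spec in self.segment_specs.items():
                cbf = sim.summary[f"CBF_{seg}_mL_s"]
                sbf = sim.summary[f"SBF_{seg}_mL_s"]
                w = layer_perfusion(seg, self.delta, cbf, sbf)
                for lay, v in w.items():
                    omega[(seg, lay)] = v
                net = thermal.build_segment_network(spec, w)
                fields[seg] = thermal.steady_state(net, T_b, spec.environment.Ta)
            tsk = {seg: f.skin for seg, f in fields.items()}
            residual = (max(abs(tsk[s] - prev_tsk[s]) for s in tsk)
                        if prev_tsk else float("inf"))
            trace.append({"iteration": it, "T_b": T_b, "residual": residual, **tsk})
            prev_tsk = tsk
            if not cfg.feedback_Tb:
                converged = True
                break
            if residual < cfg.tol_T:
                converged = True
                break
            T_b = self._venous_return_temperature(fields, omega, sim, T_b)
        summary = dict(sim.summary)
        for seg, f in fields.items():
            summary[f"T_sk_{seg}_degC"] = f.skin
            summary[f"T_core_{seg}_degC"] = f.core
        summary["T_b_degC"] = T_b
        summary["cvs_converged"] = float(sim.converged)
        return IntegratedResult(converged=converged, iterations=it, fields=fields,
                                series=sim.series, omega=omega, summary=summary,
                                trace=trace, final_state=sim.final_state, T_b=T_b)

    def _venous_return_temperature(self, fields, omega, sim, T_b: float) -> float:
        """Perfusion-weighted mixed venous temperature.

        Beds without a tissue model (the lumped peripheral path) are assumed
        to return blood at the arterial temperature; note the model carries
        no metabolic heat source, so with feedback enabled the blood pool
        relaxes slowly toward ambient.
        """
        num = 0.0
        den = 0.0
        for (seg, lay), w in omega.items():
            if w <= 0:
                continue
            f = fields[seg]
            idx = [i for i, n in enumerate(f.network.nodes) if n.name.startswith(lay)]
            t_lay = float(np.mean(f.T[idx]))
            num += w * t_lay
            den += w
        q_pr = sim.summary.get("Q_ao_mean_mL_s", 0.0) - den
        if q_pr > 0:
            num += q_pr * T_b
            den += q_pr
        return num / den if den > 0 else T_b


def run_integrated(cvs_params=None, segment_specs=None, delta=None,
                   config=None, y0=None) -> IntegratedResult:
    """One-call forward run of the integrated model (see IntegratedModel)."""
    return IntegratedModel(cvs_params, segment_specs, delta, config).run(y0=y0)


def summarize(result: IntegratedResult) -> pd.DataFrame:
    """Summary table: pressures, aortic flow, and per-segment T_sk / SBF / CBF."""
    rows = [{"quantity": k, "value": v} for k, v in sorted(result.summary.items())]
    return pd.DataFrame(rows)
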