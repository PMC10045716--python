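"""Pulsatile circuit: elastance, valves, conservation, DC oracle, trends."""

from dataclasses import replace

import numpy as np
import pytest

import hemotherm.circulation as circ


class TestElastance:
    def test_periodicity_and_bounds(self):
        h = circ.HeartParams()
        t = np.linspace(0, 60 / h.HR, 4001)
        e = circ.elastance(t, h.HR, h)
        e_shift = circ.elastance(t + 3 * 60 / h.HR, h.HR, h)
        assert np.allclose(e, e_shift, atol=1e-12)
        assert e.min() == pytest.approx(h.Emin_lv, abs=1e-6)
        assert e.max() == pytest.approx(h.Emax_lv, abs=1e-6 * h.Emax_lv)

    def test_peak_at_systolic_fraction(self):
        h = circ.HeartParams(t_sys_frac=0.35)
        T = 60 / h.HR
        t = np.linspace(0, T, 20001)
        e = circ.elastance(t, h.HR, h)
        assert t[np.argmax(e)] / T == pytest.approx(0.35, abs=0.005)

    def test_smoothness(self):
        h = circ.HeartParams()
        t = np.linspace(0, 2 * 60 / h.HR, 40001)
        de = np.diff(circ.elastance(t, h.HR, h)) / np.diff(t)
        # continuous first derivative: no jumps beyond grid resolution
        assert np.max(np.abs(np.diff(de))) < 1.0


class TestValve:
    def test_closed_under_reverse_pressure(self):
        assert circ.valve_flow(-1.0, 4.0) < 1e-6
        assert circ.valve_flow(-50.0, 4.0) == 0.0

    def test_continuous_at_zero(self):
        q = [circ.valve_flow(dp, 4.0) for dp in (-0.001, 0.0, 0.001)]
        assert q[0] < q[1] < q[2]
        assert q[2] - q[0] < 1.0

    def test_orifice_law_area_scaling(self):
        # ΔP = K·Q|Q|/A² ⇒ Q ∝ A at fixed ΔP
        q1 = circ.valve_flow(10.0, 2.0)
        q4 = circ.valve_flow(10.0, 8.0)
        assert q4 == pytest.approx(4 * q1, rel=1e-9)

    def test_forward_law_value(self):
        # K = ρ/2 in mmHg/(mL/s)²·cm⁴ units: Q = A√(ΔP/K)
        K = 1050.0 * 1e-4 / (2 * 133.322)
        assert circ.valve_flow(20.0, 4.0, eps=1e-9) == pytest.approx(
            4.0 * np.sqrt(20.0 / K), rel=1e-6)

    def test_bad_area_rejected(self):
        with pytest.raises(ValueError):
            circ.valve_flow(1.0, 0.0)


class TestRHS:
    def test_equilibrium_with_sources_zeroed(self, default_params):
        # linear valves, frozen elastance, zero source, uniform zero pressure:
        # every derivative vanishes
        h = default_params.heart
        p = replace(default_params,
                    heart=replace(h, Ppu=0.0, Emax_lv=h.Emin_lv, Emax_la=h.Emin_la),
                    valve_linear_r=1.0)
        y = np.zeros(circ.NSTATE)
        y[circ.IV_LA] = p.heart.V0_la
        y[circ.IV_LV] = p.heart.V0_lv
        dy = circ.cvs_rhs(y, 0.0, p)
        assert np.max(np.abs(dy)) < 1e-12

    def test_total_volume_conservation_identity(self, default_params):
        """Σ C·dP/dt + dV_chambers/dt equals the boundary inflow from the
        pressure source, for random states."""
        p = default_params
        pv = p.pack()
        b = p.branches
        caps = {circ.IP_PVC: b.Cpvc, circ.IP_AA: b.Caa, circ.IP_DA: b.Cda,
                circ.IP_A_CER: 1 / b.head.E0, circ.IP_AL_CER: b.head.arteriole.C,
                circ.IP_C_CER: b.head.capillary.C, circ.IP_V_CER: b.head.vein.C,
                circ.IP_A_ULB: 1 / b.upper_limbs.E0,
                circ.IP_AL_ULB: b.upper_limbs.arteriole.C,
                circ.IP_C_ULB: b.upper_limbs.capillary.C,
                circ.IP_V_ULB: b.upper_limbs.vein.C, circ.IP_CPC: b.Cpc}
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = rng.uniform(5.0, 50.0, size=circ.NSTATE)
            t = float(rng.uniform(0, 0.7))
            dy = circ.cvs_rhs(y, t, p)
            fl = circ.instantaneous_flows(y, t, p)
            dvol = dy[circ.IV_LA] + dy[circ.IV_LV]
            dvol += sum(C * dy[i] for i, C in caps.items())
            assert dvol == pytest.approx(fl["Q_pu"], rel=1e-9, abs=1e-9)

    def test_skin_resistance_perturbation_is_local(self, default_params):
        """Changing the head skin resistance affects, at the first instant,
        only the head arteriole and capillary balances."""
        p2 = default_params.with_updates(R_skin={"head": 124.0})
        rng = np.random.default_rng(7)
        y = rng.uniform(5.0, 60.0, size=circ.NSTATE)
        d1 = circ.cvs_rhs(y, 0.2, default_params)
        d2 = circ.cvs_rhs(y, 0.2, p2)
        changed = np.flatnonzero(np.abs(d1 - d2) > 1e-12)
        assert set(changed) == {circ.IP_AL_CER, circ.IP_C_CER}

    def test_nonfinite_state_named(self, default_params):
        y = np.full(circ.NSTATE, 10.0)
        y[circ.IP_DA] = np.nan
        with pytest.raises(circ.CirculationError, match="P_da"):
            circ.cvs_rhs(y, 0.0, default_params)


def _dc_oracle(params: circ.CVSParameters, rlin: float) -> dict[str, float]:
    """Independent dense linear solve of the resistive reduction of the circuit."""
    b, m, h = params.branches, params.micro, params.heart
    names = ["pvc", "la", "lv", "aa", "da", "a_cer", "al_cer", "c_cer", "v_cer",
             "a_ulb", "al_ulb", "c_ulb", "v_ulb", "J", "cpc"]
    idx = {n: i for i, n in enumerate(names)}

    def par(*rs):
        return 1.0 / sum(1.0 / r for r in rs)

    edges = [
        ("pvc", "la", h.Rpv), ("la", "lv", rlin), ("lv", "aa", rlin),
        ("aa", "a_cer", b.head.Z), ("a_cer", "al_cer", b.head.Ra),
        ("al_cer", "c_cer", par(m.core["head"], m.skin["head"])),
        ("c_cer", "v_cer", b.head.capillary.R), ("v_cer", "cpc", b.head.vein.R),
        ("aa", "a_ulb", b.upper_limbs.Z), ("a_ulb", "al_ulb", b.upper_limbs.Ra),
        ("al_ulb", "c_ulb", par(m.core["upper_limbs"], m.skin["upper_limbs"],
                                m.core["hand"], m.skin["hand"])),
        ("c_ulb", "v_ulb", b.upper_limbs.capillary.R),
        ("v_ulb", "cpc", b.upper_limbs.vein.R),
        ("aa", "da", b.Rao), ("da", "J", b.Rta),
        ("J", "cpc", par(m.core["torso"], m.skin["torso"])),
        ("J", "cpc", par(m.core["lower_limbs"], m.skin["lower_limbs"])),
        ("J", "cpc", b.Rpr), ("cpc", "pvc", b.Rpc),
    ]
    n = len(names)
    G = np.zeros((n, n))
    rhs = np.zeros(n)
    for a_, b_, r in edges:
        g = 1.0 / r
        i, j = idx[a_], idx[b_]
        G[i, i] += g
        G[j, j] += g
        G[i, j] -= g
        G[j, i] -= g
    G[idx["pvc"], idx["pvc"]] += 1.0 / h.Rpu
    rhs[idx["pvc"]] += h.Ppu / h.Rpu
    P = np.linalg.solve(G, rhs)
    return dict(zip(names, P))


class TestSimulation:
    def test_periodic_steady_state_conservation(self, default_params, default_sim):
        """Per-compartment volume drift over the final cycle stays below 0.5 %
        of that compartment's throughput."""
        assert default_sim.converged
        drift = circ.conservation_check(default_sim, default_params)
        assert max(drift.values()) < 0.005

    def test_step_size_convergence(self, default_params, default_sim):
        r2 = circ.simulate_cvs(default_params, dt=5e-5, tol_pss=0.01,
                               n_max_cycles=300, y0=default_sim.final_state)
        dmap = abs(r2.summary["MAP_mmHg"] - default_sim.summary["MAP_mmHg"])
        assert dmap < 0.1

    def test_dc_oracle_equivalence(self, default_params):
        """With elastance frozen and valves linearised, the simulated steady
        solution matches an independently assembled resistive-network solve."""
        h = default_params.heart
        rlin = 0.05
        p = replace(default_params,
                    heart=replace(h, Emax_lv=0.2, Emin_lv=0.2,
                                  Emax_la=0.15, Emin_la=0.15),
                    valve_linear_r=rlin)
        oracle = _dc_oracle(p, rlin)
        # start the simulation at the oracle solution and verify it is a
        # fixed point of the dynamics to 1e-6 mmHg
        flows = {}
        y = np.zeros(circ.NSTATE)
        y[circ.IP_PVC] = oracle["pvc"]
        y[circ.IV_LA] = p.heart.V0_la + oracle["la"] / 0.15
        y[circ.IV_LV] = p.heart.V0_lv + oracle["lv"] / 0.2
        y[circ.IP_AA] = oracle["aa"]
        y[circ.IP_DA] = oracle["da"]
        y[circ.IQ_AO] = (oracle["aa"] - oracle["da"]) / p.branches.Rao
        for pre, br in (("cer", "head"), ("ulb", "upper_limbs")):
            bb = getattr(p.branches, br)
            y[getattr(circ, f"IP_A_{pre.upper()}")] = oracle[f"a_{pre}"]
            y[getattr(circ, f"IQ_A_{pre.upper()}")] = (
                oracle[f"a_{pre}"] - oracle[f"al_{pre}"]) / bb.Ra
            y[getattr(circ, f"IP_AL_{pre.upper()}")] = oracle[f"al_{pre}"]
            y[getattr(circ, f"IP_C_{pre.upper()}")] = oracle[f"c_{pre}"]
            y[getattr(circ, f"IP_V_{pre.upper()}")] = oracle[f"v_{pre}"]
        y[circ.IP_CPC] = oracle["cpc"]
        y[circ.IQ_PV] = (oracle["pvc"] - oracle["la"]) / p.heart.Rpv
        res = circ.simulate_cvs(p, y0=y, n_max_cycles=5, tol_pss=1e-7, strict=False)
        for name, i in (("pvc", circ.IP_PVC), ("aa", circ.IP_AA), ("da", circ.IP_DA),
                        ("al_cer", circ.IP_AL_CER), ("v_ulb", circ.IP_V_ULB),
                        ("cpc", circ.IP_CPC)):
            assert res.final_state[i] == pytest.approx(oracle[name], abs=1e-6)

    def test_dc_resistance_scaling(self, default_params):
        """Doubling every resistance halves all DC flows at fixed source
        pressure (linear-circuit scaling, checked via the oracle)."""
        h = default_params.heart
        p1 = replace(default_params,
                     heart=replace(h, Emax_lv=0.2, Emin_lv=0.2,
                                   Emax_la=0.15, Emin_la=0.15),
                     valve_linear_r=0.05)
        o1 = _dc_oracle(p1, 0.05)
        b = p1.branches

        def scale_branch(br):
            return replace(br, Z=2 * br.Z, Ra=2 * br.Ra,
                           arteriole=replace(br.arteriole, R=2 * br.arteriole.R),
                           capillary=replace(br.capillary, R=2 * br.capillary.R),
                           vein=replace(br.vein, R=2 * br.vein.R))

        import hemotherm.parameters as par
        m = p1.micro
        p2 = replace(
            p1,
            heart=replace(p1.heart, Rpu=2 * h.Rpu, Rpv=2 * h.Rpv),
            branches=replace(b, Rao=2 * b.Rao, Rta=2 * b.Rta, Rpr=2 * b.Rpr,
                             Rpc=2 * b.Rpc, head=scale_branch(b.head),
                             upper_limbs=scale_branch(b.upper_limbs)),
            micro=par.MicrocirculationResistances(
                core={k: 2 * v for k, v in m.core.items()},
                skin={k: 2 * v for k, v in m.skin.items()}),
            valve_linear_r=0.1)
        o2 = _dc_oracle(p2, 0.1)
        q1 = (o1["aa"] - o1["a_cer"]) / b.head.Z
        q2 = (o2["aa"] - o2["a_cer"]) / (2 * b.head.Z)
        assert q2 == pytest.approx(0.5 * q1, rel=1e-9)

    def test_hr_raises_mean_aortic_flow(self, default_params, default_sim):
        p_hi = default_params.with_updates(HR=90.0)
        hi = circ.simulate_cvs(p_hi, tol_pss=0.01, n_max_cycles=300,
                               y0=default_sim.final_state)
        assert hi.summary["Q_ao_mean_mL_s"] > default_sim.summary["Q_ao_mean_mL_s"]

    def test_skin_resistance_lowers_branch_flow_raises_map(self, default_params,
                                                           default_sim):
        p2 = default_params.with_updates(R_skin={"head": 124.0, "hand": 300.0})
        r2 = circ.simulate_cvs(p2, tol_pss=0.01, n_max_cycles=300,
                               y0=default_sim.final_state)
        assert r2.summary["q_head_mL_s"] < default_sim.summary["q_head_mL_s"]
        assert r2.summary["q_hand_mL_s"] < default_sim.summary["q_hand_mL_s"]
        assert r2.summary["MAP_mmHg"] > default_sim.summary["MAP_mmHg"]

    def test_bad_dt_rejected(self, default_params):
        with pytest.raises(ValueError):
            circ.simulate_cvs(default_params, dt=0.01)


class TestCycleAverages:
    def _series(self, q: np.ndarray, t: np.ndarray) -> circ.HemoSeries:
        states = np.zeros((t.size, circ.NSTATE))
        flows = np.zeros((t.size, circ.NFLOW))
        flows[:, circ.FLOW_NAMES.index("q_head_core")] = q
        return circ.HemoSeries(t=t, states=states, flows=flows, period=t[-1] - t[0])

    def test_constant_flow(self):
        t = np.linspace(0, 0.8, 801)
        s = self._series(np.full(t.size, 3.3), t)
        assert circ.cycle_average_flows(s)["head"] == pytest.approx(3.3, rel=1e-12)

    def test_zero_mean_sinusoid(self):
        t = np.linspace(0, 1.0, 20001)
        s = self._series(np.sin(2 * np.pi * 5 * t), t)
        assert abs(circ.cycle_average_flows(s)["head"]) < 1e-10

    def test_matches_analytic_integral(self):
        t = np.linspace(0, 1.0, 200001)
        s = self._series(t**2, t)
        assert circ.cycle_average_flows(s)["head"] == pytest.approx(1 / 3, abs=1e-8)

    def test_short_series_rejected(self):
        t = np.linspace(0, 0.3, 301)
        s = self._series(np.ones(t.size), t)
        s.period = 0.8
        with pytest.raises(ValueError):
            circ.cycle_average_flows(s)
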