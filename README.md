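# hemotherm

Coupled lumped-parameter modelling of human hemodynamics and tissue heat
transfer, with inverse estimation of heart rate and peripheral (skin)
vascular resistance from head and hand skin temperatures.

## The problem

Fatigue changes the cardiovascular state — heart rate falls, peripheral skin
vessels constrict — and those changes show up as measurable drops in facial
and hand skin temperature. Going the other way, from observed temperatures
back to cardiovascular parameters, needs a forward model linking the two
physical domains. `hemotherm` provides that model and the inversion around
it, for physiologists and engineers working on non-contact (thermographic)
monitoring of arousal and fatigue.

## The model

**Circulation (0D Windkessel network).** The systemic circulation is an
electrical-analog circuit in mmHg/mL/s units: a constant pulmonary perfusion
pressure P_pu fills the left atrium and ventricle — time-varying elastance
chambers, P = E(t)·(V − V₀), with a normalised double-Hill E(t) and smoothed
Bernoulli-orifice valves ΔP = (ρ/2)·Q|Q|/A² — which eject into an aortic
trunk with explicit cerebral and upper-limb branches (artery → arteriole →
capillary → vein RLC compartments) and lumped torso, lower-limb and
peripheral beds. Each segment's microcirculation is a parallel pair of core
and skin resistances, so core blood flow (CBF) and skin blood flow (SBF) are
explicit currents and the *skin resistance* R_skin is a single physiological
dial per segment; the hand bed taps the upper-limb arteriole node. The
circuit is integrated (compiled RK4, fixed 0.1 ms step) to a periodic steady
state: beat-to-beat pressure change below tolerance at every node.

**Tissue heat transfer (thermal RC networks).** Each body segment (head,
torso, upper limbs, lower limbs, hand) is a one-dimensional stack of tissue
layers (core, bone, muscle, fat, skin), each layer two serial RC elements
with areal resistance r = l/λ and capacitance C = cρl. A perfused layer is
tied to the arterial blood temperature T_b through the perfusion thermal
resistance R_Eq = 1/(qρ_b c_b); the skin surface exchanges with ambient T_a
through REL = 1/h_t, where h_t = 1/(0.155·clo) + h_r + h_c. Skin temperature
is the outermost node of the steady-state solve.

**Coupling.** Cycle-averaged SBF and CBF from the circuit become per-layer
perfusions (fraction-weighted within the skin and core layer groups), which
set the R_Eq values of the thermal solve.

**Inversion (two stages).** Stage 1 calibrates per-site tissue-thickness
scale and skin resistance to awake temperatures; stage 2, with thickness
frozen, fits heart rate and the two skin resistances to fatigue
temperatures. Both are bounded trust-region least squares with seeded
multistart. Stage 2 has three parameters against two observations; the fits
carry explicit identifiability warnings (see `docs/methods.md`).

## Worked example

Apply the mean awake→fatigue parameter shifts (heart rate 76.6 → 67.96 bpm,
head skin resistance 30.4 → 42.41, hand 114.4 → 358.73 mmHg·s/mL) to the
default integrated model:

```python
from hemotherm import CVSParameters, run_integrated

awake = run_integrated(CVSParameters.default().with_updates(
    R_skin={"head": 30.4, "hand": 114.4}))
fatigue = run_integrated(CVSParameters.default().with_updates(
    HR=67.96, R_skin={"head": 42.41, "hand": 358.73}))
for label, r in (("awake", awake), ("fatigue", fatigue)):
    s = r.summary
    print(f"{label:8s} MAP {s['MAP_mmHg']:6.1f} mmHg   "
          f"aortic flow {s['Q_ao_mean_mL_s']:6.1f} mL/s   "
          f"T_sk head {s['T_sk_head_degC']:5.2f} °C   "
          f"T_sk hand {s['T_sk_hand_degC']:5.2f} °C   "
          f"hand SBF {s['SBF_hand_mL_s']:5.2f} mL/s")
```

prints

```
awake    MAP  106.5 mmHg   aortic flow  123.1 mL/s   T_sk head 34.69 °C   T_sk hand 33.39 °C   hand SBF  0.44 mL/s
fatigue  MAP   98.7 mmHg   aortic flow  113.2 mL/s   T_sk head 34.32 °C   T_sk hand 31.16 °C   hand SBF  0.14 mL/s
```

The fatigue shift lowers mean arterial pressure and aortic flow, collapses
hand skin blood flow (0.44 → 0.14 mL/s) and cools the hand far more than the
head — the mechanism by which peripheral vasoconstriction plus bradycardia
produces the asymmetric skin-temperature drop seen in fatigued subjects.

The same pipeline is scriptable from the shell:

```bash
hemotherm make-synthetic --n 3 --seed 7 --out cohort.csv
hemotherm calibrate --subjects cohort.csv --out profiles.csv --seed 7
hemotherm fit-fatigue --subjects cohort.csv --profiles profiles.csv --out fits.csv --seed 7
hemotherm report --profiles profiles.csv --fits fits.csv --out report.json
```

## Layout

```
src/hemotherm/
  parameters.py    # table-derived constants: RLC, δ_ij, R_Eq, r/C, h_t
  circulation.py   # pulsatile 0D circuit, compiled RK4, periodic steady state
  thermal.py       # layered tissue RC networks, exact steady state, transients
  coupling.py      # circuit → perfusion split → thermal fixed point
  fitting.py       # two-stage constrained inversion, cohort reporting
  synthetic.py     # ground-truth subject/cohort generation
  cli.py           # shell interface
  data/            # packaged property and circuit tables (CSV/JSON)
```

`docs/methods.md` documents the model assumptions, parameter defaults,
numerical choices and known limitations.
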