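# Methods

This note documents the models implemented in `hemotherm`, the choices made
where the design was genuinely open, the numerical settings, and what the
synthetic-data experiments do and do not demonstrate.

## Circulation model

The systemic circulation is a closed lumped-parameter (0D) circuit in
mmHg/mL/s units. Topology, from source to return:

* A constant pulmonary perfusion pressure `Ppu = 7.4 mmHg` feeds a pulmonary
  venous capacitance through `Rpu = 0.01 mmHg·s/mL`. Because `Rpu` is tiny,
  this node is pressure-pinned: the source acts as an ideal preload
  reservoir. The capacitance value itself (default 10 mL/mmHg) is therefore
  inert.
* Left atrium and ventricle are time-varying elastance chambers,
  `P = E(t)·(V − V0)`, joined by mitral and aortic valves. `E(t)` is the
  normalised double-Hill activation used widely in 0D practice, rescaled in
  time so its peak sits at the configured systolic fraction (default 0.3 of
  the cycle); atrial activation uses the same shape, shorter (0.12) and
  offset to late diastole (onset at 0.82 of the cycle).
* Valves are instantaneous smoothed orifices: forward flow obeys the
  Bernoulli law `ΔP = K·Q|Q|/A²` with `K = ρ_b/2` in circuit units and the
  printed effective areas (4 cm²); the opening is a softplus ramp over
  ~0.02 mmHg, so flow is smooth in time and exponentially close to zero
  under reverse pressure. The printed valve inertances (0.0004–0.0005
  mmHg·s²/mL) are not given dynamic states; neither are the
  arteriole/capillary/vein inertances (≤ 0.003 mmHg·s²/mL, sub-millisecond
  time constants). The aortic (`Lao`) and branch-artery inertances are kept.
* The aortic trunk (`Caa`, `Cda`, `Rao`, `Rta`) carries explicit cerebral
  and upper-limb branches. A branch artery specified as `E0:Z:R:L` is
  realised as a compliance `1/E0` fed through the series characteristic
  impedance `Z`, ahead of the `R–L` segment — the common reading of
  elastance-plus-impedance artery compartments, isolated in one constructor.
* Microcirculation: the single printed arteriole resistance of each segment
  equals (to the printed precision) the parallel combination of that
  segment's core and skin microcirculation resistances — e.g. upper limbs
  30∥189 = 25.89, torso 2∥68 = 1.94. The circuit therefore carries the
  core/skin pair explicitly, which makes core blood flow (CBF) and skin
  blood flow (SBF) observable currents and makes the skin resistance the
  natural inverse-problem parameter. The hand bed (core 539, skin
  114.4 mmHg·s/mL by default) taps the upper-limb arteriole node; its core
  value is set so the hand's core/skin flow ratio matches its tabulated
  layer perfusions (0.14/0.66 mL/s), since no hand resistances are
  tabulated.
* Torso, lower-limb and peripheral beds hang off a purely resistive
  junction behind `Rta` (solved algebraically inside the right-hand side),
  and all beds drain into a peripheral venous capacitance `Cpc` that
  returns to the pulmonary node through `Rpc`, closing the loop.

### Heart defaults and what the circuit can and cannot reproduce

The elastance bounds are not tabulated inputs; they were calibrated once so
that mean aortic pressure at the resting heart rate (76.6 bpm) lands at
~106.6 mmHg with the tabulated resistances, then frozen:
`Emax_lv = 5.0`, `Emin_lv = 0.05 mmHg/mL` (atrium 0.25/0.15), `V0 = 10/4 mL`.

Two consequences of the printed parameter set are worth stating plainly:

* The tabulated peripheral and torso resistances put the total systemic
  resistance near 0.8 mmHg·s/mL, so a ~106 mmHg mean pressure forces a
  cardiac output near 7.4 L/min — high for rest. Branch flows sit where the
  tables put them (cerebral ~4.5 mL/s given the printed 15 mmHg·s/mL
  characteristic impedance).
* With an ideal constant-pressure preload source, stroke volume is nearly
  independent of rate, so mean pressure falls almost proportionally with
  heart rate. The awake→fatigue mechanism run consequently overshoots the
  observed mean-pressure drop (≈ −7.5 mmHg simulated vs −3.4 mmHg observed
  for the 76.6→67.96 bpm shift); the direction and the relative ordering of
  all effects are correct. The aortic pulse pressure is likewise
  exaggerated by the small tabulated aortic compliances (0.1 mL/mmHg).

## Tissue thermal model

Each segment is a 1D chain of layers, innermost→outermost: core, bone,
muscle, fat, skin for head and torso; bone, muscle, fat, skin for the limbs
and the hand. Every layer contributes **two serial RC elements** whose areal
values are taken verbatim from the property table (the printed values are
treated as authoritative; some fat rows are not reproducible from r = l/λ with
the tabulated thicknesses, so the formula path is used only for non-default
geometry — in practice, for the hand, which has no tabulated thermal rows
and borrows upper-limb layer properties with hand thicknesses). The
epidermis is a third serial element on the skin layer. Skin temperature is
the outermost node.

Attachments: each perfused element node is tied to the arterial temperature
`T_b` (default 37 °C) through twice the layer's perfusion thermal
resistance `R_Eq = 1/(ωρ_b c_b)` (two nodes in parallel recover `R_Eq`);
ω = 0 leaves the branch open. The outermost node reaches ambient through
the outer element resistance in series with `REL = 1/h_t`, with a parallel
isolation-loss resistance `Re = 50·REL` (routing < 2 % of the surface flux;
no value is tabulated, so the loss is made explicit and small).

The surface coefficient follows the printed relation
`h_t = 1/(0.155·clo) + h_r + h_c` — note the clothing term *adds*
conductance in this form; it is implemented as printed, and bare skin is
the `clo → ∞` limit. Defaults: `T_a = 25 °C`, `h_r = 4.7`, `h_c = 3.1
W/m²·°C` (standard indoor values); head and hand bare, torso and limbs
`clo = 1`. Evaporative exchange has no governing equation in the model and
is excluded by default (an additive constant term is available).

Steady state is an exact dense linear solve of the resistive balance;
transients use unconditionally stable implicit Euler. Blood
thermophysical defaults: ρ_b = 1050 kg/m³, c_b = 3850 J/(kg·°C)
(standard literature values; configurable).

## Coupling

One pass: circuit to periodic steady state → cycle-averaged CBF/SBF per
segment → per-layer flows → thermal steady state per segment. Layer flows
are split group-wise: the skin group (fat + dermis) shares SBF and the core
group (core + muscle) shares CBF, each weighted by the tabulated perfusion
fractions renormalised within the group. At the default resistances this
reproduces the plain δ_ij·q_i distribution exactly (the resistance table
was evidently built from the perfusion table), and it keeps the
R_skin → T_sk mechanism physical when the inverse stage moves R_skin away
from the defaults.

Nothing feeds back from tissue to the circuit, so without arterial-
temperature feedback a single pass *is* the fixed point. The optional
feedback mode updates `T_b` from the perfusion-weighted venous return and
iterates (tolerance 0.01 °C on skin temperatures, ≤ 20 iterations); since
the model carries no metabolic heat source, the blood pool then relaxes
slowly toward ambient — the mode exists for completeness and is off by
default. Beat-averaged (not instantaneous) flows drive the thermal side,
consistent with matching steady mean temperatures.

## Inverse estimation

Stage 1 (awake): per-site multiplicative thickness scale and skin
resistance are fitted to the awake head and hand temperatures. A single
scale per site is used rather than 4–5 free layer thicknesses: two
temperatures cannot identify five thicknesses. Stage 2 (fatigue): with
thickness frozen, heart rate and both skin resistances are fitted to the
fatigue temperatures, heart rate initialised at the awake value.

Both stages use bounded trust-region least squares (`scipy.optimize.
least_squares`, trf — an interior-point-style constrained local method)
with seeded multistart (default 5 starts, stopping early once a start fits
to ~0.03 °C, since further starts can at best tie). Bounds: thickness scale
0.5–1.5, skin resistance 5–1000 mmHg·s/mL, heart rate 40–120 bpm. The trust
region is scaled by expected physiological variation (heart rate 2.5 bpm,
thickness 8 %, resistance 30 %), which keeps the optimizer path physical on
an objective that is otherwise flat along whole directions.

**Identifiability, stated honestly.** Stage 2 has three parameters and two
observations: for every heart rate in a neighbourhood there exist
resistances fitting both temperatures exactly, so the *data do not identify
heart rate* — the returned value reflects the optimizer's path from its
initial point. Stage 1 has the analogous scale/resistance confound within
each site. Every fit object carries explicit warnings to this effect, and a
single-site observation set adds a second warning. In synthetic-cohort
recovery experiments the practical consequence is: effect *directions*
(heart rate down, resistances up) are recovered for all subjects; skin
resistances are recovered with median error ~13–15 %; fitted heart rate
tracks its initial value to within a few bpm and carries a systematic bias
of roughly +5 bpm relative to the generating truth. Recovering heart rate
to ±2 bpm from two temperatures alone is not attainable with this (or any)
steady-state forward model; a third observable or a rate prior would be
needed.

## Synthetic subjects

The generator emulates the structure of the motivating awake/fatigue
cohort: awake heart rate ~ N(76.6, 4²) bpm truncated to [65, 90], fatigue
rate lower by U(5, 12) bpm; awake skin resistances log-normal around the
cohort means (head 30.4, hand 114.4 mmHg·s/mL, σ_log = 0.15); fatigue
raises them by U(1.2, 1.6) (head) and U(2.7, 3.5) (hand); thickness scales
~ N(1, 0.08²). Observations are the forward model at the truth plus i.i.d.
Gaussian noise, sd 0.05 °C (≈ thermal-camera repeatability), bit-
reproducible per subject seed.

What it does not emulate: real thermal images (region-of-interest tracking,
emissivity, motion), within-state temperature drift, inter-segment
anatomical covariance, or any deviation between this forward model and real
physiology. Passing recovery tests therefore demonstrates the *inversion
machinery* under the model's own assumptions, not field accuracy.

## Numerical choices

* Circuit integration: compiled (numba) classical RK4, fixed step
  dt = 0.1 ms, exactly resolving the cycle (step = period/round(period/dt)).
  The stiffest retained time constants are ~1–2 ms, comfortably stable at
  this step; halving dt moves mean aortic pressure by < 0.01 mmHg.
* Periodic steady state: beat-to-beat absolute pressure change < tol at all
  capacitive nodes; tol 0.1 mmHg for interactive runs, 0.01 mmHg where
  conservation is being measured, 0.05 mmHg inside the optimizer (with
  warm starts from the previous solution, a parameter step re-converges in
  a handful of beats).
* Startup: all pressures 10 mmHg, chambers at V0 + 50 mL, zero inductor
  flows; convergence is to the same periodic orbit regardless.
* Thermal solves are exact (dense `numpy.linalg.solve`, networks ≤ ~13
  nodes per segment); degenerate networks (a node unreachable from every
  source) are rejected by a connectivity check naming the node.
* Finite-difference steps in the optimizer are 5 % relative — far above the
  ~1e-3 °C numerical noise floor of the periodic-steady-state solve.
* Problem sizes: the recovery experiment uses 10 subjects (40 observations,
  ~90 forward solves per subject); the oracle comparison uses 50 random
  networks of 3–30 nodes; diagnostics run on single cycles of ~7,800 output
  steps. A full test run plus the reproduction script completes in a few
  minutes on one CPU.

## Known limitations

* No baroreflex or autonomic control, no right heart or pulmonary
  dynamics, no vessel nonlinearity beyond the valve law; the preload source
  is ideal, making output nearly proportional to rate (see above).
* No metabolism, sweating, shivering or evaporative regulation in the
  thermal model; inter-segment conduction defaults to zero (no conductances
  are tabulated) — segments couple only through the shared arterial
  temperature and the circuit.
* The tabulated parameter set is internally inconsistent in places (branch
  impedances vs. tabulated segment perfusions; some thermal fat rows); the
  package takes the printed element values as authoritative and documents
  each such choice where it is made.
* Heart-rate identifiability in the two-temperature inverse problem is
  structural, not numerical; see above.
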