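# Methods

## Model

`csfcircuit` simulates cerebrospinal-fluid (CSF) production, circulation and
absorption as a fixed-topology electrical network, in the classical
hydraulic analogy: node voltages are pressures (Pa), branch currents are
flows, capacitors are compliances and ideal diodes are one-way valves. The
network is

```
source ──R1── A ──R2── C ──R3── V ──R4── ref
                       │
                   Rf + D_f            Cai: A ↔ IC
                       │               Cvi: V ↔ IC
                       IC              Ctiss: IC ↔ ref
                       │
          (Ro + D_o) ∥ (Rshunt + D_sh)
                       │
                      P_vs (ref)
```

`A`, `C`, `V`, `IC` are the arterial, capillary, venous and intracranial
nodes. The formation branch (`Rf` plus diode) is choroid-plexus secretion;
the absorption branch (`Ro` plus diode) is the arachnoid granulations
draining into the sagittal sinus; the shunt is a second, valved drainage
path in parallel. Both drainage branches terminate at the sinus pressure
`P_vs`, which defaults to the reference (0 Pa): the sinus is the downstream
end of the absorption pathway, and its pressure is treated as externally
fixed rather than as part of the modelled venous node. This termination was
a genuine design choice; returning the drained CSF current into the venous
node instead shifts the healthy steady ICP from ≈706 Pa to ≈861 Pa and
breaks the otherwise excellent agreement with the reference steady-state
values, so the fixed-sinus termination is used (and `P_vs` is configurable).

### State and equations

Only the three capacitors carry state: `u_ai = P_a − P_ic`,
`u_vi = P_v − P_ic`, `u_ic = P_ic`. The capillary node has no compliance
and is eliminated algebraically at each instant from its current balance,
with the formation valve's conduction state resolved by a try-conducting/
fall-back-blocked rule (the balance is strictly decreasing in `P_c`, so the
consistent solution is unique). The three differential equations are the
current balances at `A` and `V` and, for the intracranial node, the
rigid-cranium volume-conservation statement: the arterial, venous, tissue
and CSF volume rates sum to zero. Because `dP_ic/dt` is *defined* by that
identity, conservation holds along every trajectory to machine precision —
the test suite verifies the assembled traces satisfy it to 1e−6 of peak
flow, which checks the implementation, not the physics.

Valves are ideal diodes: branch flow `max(ΔP, 0)/R`, zero forward drop,
zero reverse leakage, and exactly zero flow at `ΔP = 0`. The resulting
right-hand side is continuous and piecewise linear, so no event detection
is needed.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| R1 | source series (waveform-shaping) resistance | 6 | Ω-analog |
| R2, R3, R4 | arterial / capillary / venous resistance | 2.5 / 3.25 / 3 | Ω-analog |
| Rf | formation (choroid plexus) resistance | 5 | Ω-analog |
| Ro | CSF outflow resistance | 1 (5 moderate, 10 severe) | Ω-analog |
| Rshunt | shunt resistance | 1.11111 | Ω-analog |
| Cai, Cvi, Ctiss | compliances | 0.1 each | F-analog |
| src_offset | mean arterial drive | 16000 | Pa |
| src_amp1, src_amp2 | pulsatile amplitudes | 17, 12.5 | Pa |
| src_f1, src_f2 | pulsatile frequencies | 1, 2 | Hz |
| P_vs | sinus (drainage terminal) pressure | 0 | Pa |

The scale anchor is that 1 Ω-analog of outflow resistance corresponds to
≈8 mmHg/ml/min hydraulically, and 133.322 Pa = 1 mmHg. The compliances are
interpreted as 0.1 F-analog (from "100 mF"), giving RC time constants of
0.1–1 s, consistent with a 1 Hz cardiac drive and multi-second pressure
transients. Two deliberate oddities of the source are kept as specified
rather than "corrected": `R1` has no physiological gloss beyond shaping the
waveform, and the pulsatile amplitudes (±30 Pa on a 16 kPa offset) are far
smaller than a physiological pulse pressure — the model's reported
quantities are means, which these amplitudes barely affect.

The time-varying shunt law `Rshunt(t) = 15 e^(−0.3 t) (1.2 + sin t)`
(amplitude Ω, decay 1/s, `t` in radian-seconds) emulates a failing valve:
the sinusoid is irregular opening/closing, the decaying envelope is the
transition into over-drainage. The offset must exceed 1 so the resistance
stays positive for finite `t`.

## Numerics

- Integrator: `scipy.integrate.solve_ivp`, LSODA, `rtol 1e−8`,
  `atol 1e−10`, `max_step 0.1 s` (so the 2 Hz forcing is always sampled),
  output resampled on a uniform 0.01 s grid.
- Runs are 60 s from a zero initial state; the scalar "ICP" of a run is the
  arithmetic mean of `P_ic` over the final 10 s (≥10× the largest RC time
  constant past the transient, and a whole number of forcing periods). The
  failing-shunt experiment instead runs 15 s from the untreated severe
  steady state — the shunt is switched on against an already elevated ICP.
- A DC steady-state oracle solves the 4-node linear current balance with
  capacitors open, the source at its offset and all diodes assumed
  conducting, then verifies the assumption (every branch ΔP ≥ 0) and
  raises otherwise. With pulsatility switched off the integrator lands on
  this analytic fixed point to better than 0.1%; with the default
  pulsatile source the windowed means differ from it by ~1e−4 %.
- Percent elevations always use a freshly simulated healthy baseline under
  identical solver settings, and shunt efficiencies additionally use the
  same-pathology no-shunt run, so discretisation error cancels rather than
  compounds. Nothing is compared against hard-coded reference pressures at
  run time.
- `resistance_for_efficiency` brackets and Brent-solves the monotone map
  from constant shunt resistance to simulated efficiency; attainable
  targets lie between the no-shunt floor (≈19%, the healthy-offset term of
  the efficiency definition) and the over-drainage ceiling (≈119%, where
  the ICP is driven to zero).
- Compartment volume rates use central finite differences on the output
  grid; their sum vanishes up to O(dt²) finite-difference error in the
  periodic regime (~1e−4 of the formation flow), but not during the first
  fraction of a second of an unresolved start-up transient.

## Design choices and known limitations

- The efficiency definition's three ICPs are: healthy = the `Ro = 1`
  no-shunt run, before = the same-pathology no-shunt run, after = the
  pathology-plus-shunt run. Under this reading the simulated sweep
  reproduces the reference efficiency column to well under 1 percentage
  point. A shunt of 1.25 Ω is sometimes labelled "90% efficient", but the
  definition applied to its own steady ICPs gives ≈98%; this package keeps
  the resistance and pressure values as anchors and does not reproduce
  that label.
- Ideal diodes leave a small systematic offset (~0.3–0.5%) between this
  implementation's steady ICPs and the reference values, consistent with a
  non-ideal diode (finite forward drop) in the original circuit
  realisation; no diode parameters are available, so no attempt is made to
  reverse-engineer them. All comparisons pass at 1% regardless.
- From an all-zero initial state the CSF compartment initially *drains*
  rather than fills (the intracranial node charges capacitively before
  formation flow is established); the physically meaningful
  hydrocephalus-onset experiment starts from the healthy steady state and
  raises `Ro`, and that is what the fill-rate test exercises.
- Out of scope, as in any lumped model of this family: the spinal
  compartment's compliance and absorption, lymphatic drainage, cerebral
  autoregulation, posture and brain-size effects, and any nonlinear
  pressure dependence of `Ro`. The topology is fixed and parameterised,
  not a general netlist engine; there is no Shockley-style diode model.
- The Poiseuille helper maps catheter geometry (viscosity, length, radius)
  to hydraulic resistance; translating that into the Ω-analog scale beyond
  the 1 Ω ≈ 8 mmHg/ml/min anchor would require CSF viscosity and catheter
  dimensions the model does not presume.
- Everything here is a deterministic circuit abstraction: passing tests
  show internal consistency and agreement with the reference circuit's
  steady values, not validation against clinical ICP recordings, which
  contain autoregulatory, respiratory and postural dynamics this network
  does not represent.
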