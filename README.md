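# hemigait

A computational model of the spinal circuits that set cycle, stance and
swing durations in cat hindlimb locomotion, and of how those durations
change after a lateral (one-sided) thoracic spinal cord hemisection.

The package is aimed at researchers in locomotor neuromechanics and
spinal-cord-injury physiology who want a tested, scriptable implementation
of the bilateral rhythm-generator model: two flexor–extensor half-center
oscillators (activity-based populations with persistent-sodium dynamics)
coupled by commissural interneuron pathways (V0D, V2a→V0V→Ini, V3), driven
by speed-dependent supraspinal drives and by stance-phase sensory feedback
under presynaptic inhibition.

## The model in brief

Each population follows

    C dV/dt = −g_NaP m∞(V) h (V−E_Na) − g_L (V−E_L) − g_E (V−E_synE) − g_I (V−E_synI)
    dh/dt   = (h∞(V) − h) / τ_h(V)

with sigmoidal activation/inactivation and output `f(V)` normalised to
[0, 1].  Per side, the flexor half-center RG-F and extensor half-center
RG-E inhibit each other through relays InF and InE.  Supraspinal drive α
(flexor side, scaled with treadmill speed as α = a₀ + a₁β) and γ (extensor
side, constant) set excitability.  Two feedback signals per limb operate
during stance only: SF-E1 = k_E1·s, a ramp over the stance-progress
coordinate s (ds/dt = β), models hip-flexor stretch afferents and triggers
the stance→swing transition; SF-E2 = k_E2·(extensor output) models
extensor force (group Ib) feedback and reinforces weight support.  Drive
presynaptically inhibits ipsilateral feedback by the factor
max(0, 1 − k_PSI·α).

A **right hemisection** zeroes the right-side drives (and hence their
presynaptic inhibition of right-limb feedback); nothing else changes.  A
**transection** zeroes all four drives.  Depending on drive, an isolated
rhythm generator operates as a non-oscillatory *state machine* (feedback
must trigger flexion), a *flexor-driven* oscillator (intrinsic NaP
bursting), or a classical *half-center* (mutual inhibition required); the
package classifies these regimes directly from simulation.

## Worked example

```python
from hemigait import ModelConfig, build_network, integrate
from hemigait.phases import analyze_result

config = ModelConfig()
network = build_network("hemisected", config.circuit)
result = integrate(network, (0.4, 1.0), config)   # left slow / right fast
for side in ("left", "right"):
    s = analyze_result(result, side, config)
    print(side, round(s["cycle_mean"], 3), round(s["stance_mean"], 3),
          round(s["swing_mean"], 3), round(100 * s["duty_mean"], 1))
```

prints

```
left 1.56 1.255 0.305 80.4
right 0.778 0.352 0.426 44.6
```

— on the fast belt the ipsilesional (right) hindlimb's stance has
collapsed below its swing (duty factor 44.6% < 50%): with the right
supraspinal drive gone, the full-gain speed-dependent stretch feedback
triggers flexion early, while the contralesional limb keeps long, slow
steps.  Sweeping the fast belt from 0.5 to 1.0 locates the stance/swing
crossing near β_R ≈ 0.6.  More narrated scripts live in `examples/`:
single split-belt simulations, tied-belt sweeps before/after hemisection,
operating-regime classification, and the synthetic-cat ANOVA stage.

The analysis pipeline mirrors an experimental workflow: phase events are
threshold crossings of the flexor output (flexion = swing), cycles are
tabulated from stance onset to stance onset with swing = cycle − stance
exactly, and a synthetic repeated-measures dataset generator (cat × state
× speed × cycle, 5–6 cats, 0.4–1.0 m/s) feeds a classical two-factor
(state × speed) repeated-measures ANOVA plus a sign-level
simulation-vs-data agreement report.

## Layout

- `src/hemigait/network.py` — populations, connectivity, hemisection /
  transection transforms, JSON round-trip
- `src/hemigait/feedback.py` — limb state machine, SF-E1/SF-E2,
  presynaptic inhibition
- `src/hemigait/engine.py` + `_kernel.py` — belt protocols, speed→drive
  mapping, compiled closed-loop RK4 integrator, speed sweeps
- `src/hemigait/phases.py` — phase events, step-cycle tables, crossing
  speed, operating-regime classification
- `src/hemigait/synth.py` — synthetic cat step-cycle datasets
- `src/hemigait/stats.py` — repeated-measures ANOVA and the agreement
  report
- `src/hemigait/cli.py` — `hemigait simulate | synthesize-data | stats`

See `docs/methods.md` for the modelling choices, calibration rationale and
known limitations.
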