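# Methods

## Model

### Populations

The circuit contains ten populations per side: the rhythm-generating
flexor (RG-F) and extensor (RG-E) half-centers, their inhibitory relays
InF and InE, and the commissural-pathway interneurons V0D, V2a, V0V, Ini,
V3-F and V3-E.  All populations are activity-based (non-spiking): a
membrane voltage V with conductance-based synaptic input, and a normalised
output f(V) that is 0 below `Vout_min`, 1 above `Vout_max` and linear in
between.  The half-centers are conditional bursters carrying a persistent
sodium current g_NaP·m∞(V)·h·(V−E_Na) with instantaneous activation and a
slow inactivation variable h; relays have g_NaP = 0 and h fixed at 1.

Reversal potentials, capacitance and leak are shared (C = 20 pF,
g_L = 4.5 nS, E_L = −64 mV, E_Na = 50 mV, E_synE = −10 mV,
E_synI = −75 mV).  The half-centers use Vm_half = −40 mV, km = −6 mV for
activation.  Inactivation kinetics differ by role and are central to the
model's behaviour:

* **Flexor** (Vh_half = −45 mV, kh = 4 mV, τ₀ = 6000 ms, Vτ = −40 mV,
  kτ = 5.5 mV): the τ_h(V) peak sits at the plateau voltage of a weakly
  driven burst, so a flexion episode triggered from a well-recovered state
  is long-lasting, while recovery at hyperpolarised voltages is fast
  (τ_h ≈ 450 ms near rest).  A weakly driven flexor therefore behaves as a
  *flexion hold* that outlasts the moment it is switched off by
  inhibition, which is what lets the deafferented-drive (hemisected) side
  spend most of its cycle in swing at high belt speed.
* **Extensor** (Vh_half = −40 mV, kh = 4 mV, τ₀ = 2000 ms, Vτ = −30 mV,
  kτ = 10 mV): inactivation is deep and develops throughout the extensor
  plateau.  The declining extensor output, relayed through InE, forms a
  falling inhibitory barrier on the ipsilateral flexor; the time at which
  the flexor's drive overcomes this barrier sets the stance duration.
  Higher drive ⇒ earlier escape ⇒ shorter stance, which produces the
  speed-dependent compression of stance with roughly constant swing that
  characterises cat locomotion.

The commissural interneurons (V0D, V2a, V0V, Ini, V3-F, V3-E) use a more
sensitive output range (−55 to −20 mV) so that modest drive produces
graded activity; InF and InE keep the default range.

### Connectivity

Within a side: RG-F→InF⊣RG-E and RG-E→InE⊣RG-F (mutual inhibition through
relays).  Between sides: V0D carries direct crossed inhibition of the
contralateral RG-F; V2a (drive- and flexor-activated) →V0V→contralateral
Ini⊣RG-F carries indirect, drive-gated crossed inhibition — after a right
hemisection the right-to-left limb of this pathway falls silent because
right V2a loses its drive; V3-F carries weak crossed flexor-flexor
excitation, V3-E crossed extensor-extensor excitation and the crossed
action of load feedback (SF-E2 also excites the ipsilateral V3-E).

Supraspinal drives: α excites the ipsilateral RG-F (weight 1.55), the
contralateral RG-F (0.1; the crossed branch is anatomically present but
functionally minor — see Calibration), and the ipsilateral V2a; γ = 0.5
excites the ipsilateral RG-E (weight 10).  The treadmill-speed mapping is
α = a₀ + a₁β with a₀ = −0.017, a₁ = 0.717, so α runs from ≈0.27 at
0.4 m/s to ≈0.70 at 1.0 m/s; γ is speed-independent.  Hemisection zeroes
α_R and γ_R; transection zeroes all four.  No other parameter changes with
condition.

### Feedback

Each limb is a two-state machine (stance/swing) driven by the ipsilateral
flexor output through a threshold at 0.1 with a ±0.05 hysteresis band.
During stance the progress coordinate integrates ds/dt = β (s in belt
lengths, time in seconds) and resets at stance onset.  SF-E1 = k_E1·s
(k_E1 = 0.65) excites the ipsilateral RG-F (weight 4) and weakly inhibits
the contralateral RG-F (0.2); SF-E2 = k_E2·(extensor output) (k_E2 = 1)
excites the ipsilateral RG-E (8) and V3-E (1.5).  Both are zero during
swing.  Presynaptic inhibition scales both ipsilateral channels by
max(0, 1 − k_PSI·α) with k_PSI = 3.5: above α ≈ 0.29 the intact side's
feedback is fully suppressed, so the intact model is drive-paced while a
hemisected side receives its feedback at full gain — the central
asymmetry of the model.

The stance-progress ramp stands in for hip extension (no musculoskeletal
model is included), and extensor output stands in for limb load; both are
deliberate simplifications.

## Simulation and analysis

Fixed-step RK4 at dt = 0.1 ms integrates all 20 populations and the two
limb state machines in closed loop (feedback conductances are frozen
within a step; they evolve on the ~100 ms limb time scale).  Runs last
50 s with the first 10 s discarded; outputs are recorded every 1 ms.  The
integrator is deterministic; the default initial state is an antisymmetric
seed (left flexor depolarised, right at rest) selecting the alternating
gait branch.  Halving dt changes steady-state cycle durations by less than
0.1%, and a decoupled relay reproduces the closed-form exponential
relaxation to 1e-6 relative accuracy (both are regression-tested).

Phase events are hysteretic threshold crossings of RG-F output
(flexion = swing), refined by linear interpolation between samples.
Cycles run from stance onset to stance onset; swing = cycle − stance
exactly; means and SDs are taken over all complete cycles after the
transient.  A sweep point is classified rhythmic when there are ≥3
crossings and the period coefficient of variation is below 5%.  The
stance/swing crossing speed is linearly interpolated at the first sign
change of (stance − swing) along the sweep.  Operating regimes are
classified by simulation of one isolated rhythm generator: non-oscillatory
⇒ state machine; oscillatory and robust to silencing InE→RG-F ⇒
flexor-driven; otherwise half-center.  With the calibrated parameters the
sequence along increasing drive is state-machine (α ≲ 0.3), flexor-driven
(α ≈ 0.35–0.6), half-center (α ≳ 0.7).

## Synthetic experimental datasets

The statistical stage is exercised with synthetic step-cycle datasets
mirroring the experimental design: 5 cats (tied-belt) or 6 (split-belt),
two states (intact, hemisected), speeds 0.4–1.0 m/s in 0.1 m/s steps
(fast belt 0.5–1.0 in split protocols), 15 cycles per cell.  Mean cycle
and stance durations follow hyperbolic baselines T₀(v) = 0.317 + 0.233/v
and S₀(v) = 0.068 + 0.207/v (≈0.90 s cycle at 0.4 m/s, ≈0.55 s at
1.0 m/s, duty 65→50%), a per-cat multiplicative intercept (SD 5%) shared
across states, and additive per-cycle residuals (SD 20 ms, truncated at
0.1 s).  Hemisection effects are applied to per-side means either as
multiplicative stance/swing shifts or as a cycle-preserving transfer of
duration from stance to swing.  The generator emulates the repeated-
measures *structure* and plausible magnitudes of real recordings, not
their autocorrelation, missingness or kinematic detail, so passing tests
validate the pipeline's statistics, not cat biology.

The two-factor (state × speed) repeated-measures ANOVA averages cycles
within cat × state × speed, partitions sums of squares into subject,
state, speed, state × speed and the corresponding effect-by-subject error
terms, and tests each effect against its own interaction with subject at
P < 0.05.  No sphericity correction is applied by default (the state
factor has two levels); a Greenhouse–Geisser correction is available
behind a flag.  The implementation is checked to 1e-8 relative agreement
against statsmodels' AnovaRM and an independently coded loop oracle, and
its empirical type-I error under a null generator is calibrated to
0.03–0.07 over 1000 replicates.

The agreement report compares signs of hemisection effects: the simulated
sign is the grid-mean of (hemisected − intact) per side and variable, the
data sign is the marginal state difference gated by the ANOVA (p ≥ 0.05 ⇒
no direction).  Both sides of the comparison apply the same 2% relative
dead-band, so formally significant but negligible differences are not
scored as directions; this keeps the report's null cells stable, since a
type-I fluke in the ANOVA almost never coincides with a ≥2% marginal
difference under the calibrated noise levels.

## Calibration rationale and what the model does and does not reproduce

Published descriptions of this circuit are qualitative, so all synaptic
weights, gains and the burster kinetics are calibration parameters.  They
were tuned against the model's target behaviours: the three-regime
taxonomy with flexor-driven rhythm available from α = 0.35 (without any
feedback the intact network is rhythmic from α ≈ 0.26); speed-modulated
tied-belt locomotion in the intact state; feedback-sustained stepping in
the transected state; and the split-belt predictions for the hemisected
state.  The calibrated model reproduces the headline split-belt result
robustly: with the ipsilesional limb on the fast belt, its stance and
swing durations cross near β_R ≈ 0.6 and the duty factor falls to ≈45%
at β_R = 1.0, while the contralesional limb keeps long cycles.

Two quantitative aspects fall short of the biological target and are
documented here deliberately.  First, the contralesional side of the
hemisected model is only approximately invariant: near the slow end of
the speed range the network operates close to its rhythmicity boundary,
where the cycle duration is steeply sensitive to small input changes, so
removing the (small) crossed drive and coupling from the lesioned side
shifts left-side cycle durations by ~5–25% rather than the few percent
seen in cats; for the same reason left and right sides do not phase-lock
1:1 at every tied-belt speed.  Second, in the left-fast/right-slow
protocol the simulated durations vary more across the sweep than the
near-constancy observed experimentally.  Flattening the period–drive
relation near the slow operating point (e.g. by an extensor clock with an
accelerating, rather than settling, adaptation) is the natural next step;
the present parameterisation prioritises the regime taxonomy and the
fast-belt asymmetry, which are the model's discriminating predictions.

## Numerical and design choices

* Belt-speed parameters β are dimensionless and numerically equal to belt
  speed in m/s, for direct axis comparability.
* 50 s runs with a 10 s discard give <1% estimator noise on mean
  durations; doubling the discard changes means by <1%.
* Phase threshold 0.1 with 0.05 hysteresis prevents chatter at burst
  edges of the normalised outputs.
* The flexor-output convention (flexion = swing) defines limb phase both
  for the feedback state machine and for analysis, so simulated "paw
  contact" is the downward crossing of the flexor threshold.
* Drives enter as conductances through condition-dependent connection
  weights; hemisection/transection are implemented as weight transforms
  so that the intact/hemisected difference is exactly the right-drive
  rows of the connection list.
* The cycle-averaged unit for the ANOVA is the cat (cycles are averaged
  within cat × state × speed first); speed is treated as a categorical
  factor with 6–7 levels.
* Degenerate inputs: traces without threshold crossings yield an empty
  event list flagged non-rhythmic; tables with fewer than two complete
  cycles are empty; unbalanced ANOVA designs are rejected with the
  offending cells named.

## Limitations

No musculoskeletal or pattern-formation layer; no forelimb–hindlimb
coordination; no post-injury plasticity; no spiking or noise — the model
addresses steady-state temporal structure of hindlimb locomotion only.
Gaits other than left-right alternation (hopping, bounding) are outside
the calibrated basin and not explored.
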