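# Model and methods

## Scope

`crucell` is a stochastic, calcium-release-unit (CRU) resolved model of a
human ventricular cardiomyocyte, together with the analysis layer needed to
study heart-failure (HF) remodeling of excitation–contraction coupling:
action-potential and Ca²⁺-transient metrics, Hill-predicted force, SR
fractional release, EC-coupling gain under voltage clamp, and Ca²⁺ spark
statistics. The published quantities the model is anchored to are the control
conductances and their HF scalings (G_K1 = 0.238, G_to = 0.618,
G_Kr = 0.0488, G_Ks = 0.0224 mS/µF; kryr⁺ = 14; Ap = 150 µM;
G_NCX = 1000 µA/µF; reductions of 56/67/20/28%, +50% RyR sensitivity,
−50% SERCA, +100% NCX), the CRU composition (49 RyR2 and 9 LCCs per CRU,
20 000 CRUs in the reference cell), the pacing and voltage-clamp protocols,
and the force/fractional-release equations. All rate constants, volumes and
buffer parameters are **reconstructed**: they are not published alongside
those values, and were chosen once so that the control cell sits in the
documented qualitative regime (resting RyR open probability ≈ 0, peak
systolic whole-cell open fraction 0.1–0.4, Ca²⁺-transient peak near 1 µM,
time-to-peak ≈ 0.02 s, APD90 ≈ 230 ms). They live in `gating.py` and
`params.py` and are all overridable through the run configuration.

## Structure of the model

Each CRU is a point dyad: a dyadic subspace (~10⁻¹⁸ L) facing a junctional
SR (JSR) compartment, holding one 49-channel RyR2 cluster and 9 L-type
channels. CRUs couple to four shared pools: bulk myoplasm, network SR (NSR),
the membrane potential, and fixed Na⁺/K⁺ gradients. Simulating `n_cru` <
20 000 CRUs keeps per-CRU physics identical and weights each simulated CRU
by `20000/n_cru` in whole-cell sums, so whole-cell flux densities are
unbiased and only their sampling noise grows.

**RyR2 (3 states).** closed → open with rate
`kryr⁺ · k_base · ca² / (ca² + K_act²)` (K_act = 150 µM, so the activation is
effectively ∝ ca² over the dyadic range and saturates only during full
release); open → closed (0.5 ms⁻¹), open → refractory (0.06 ms⁻¹),
refractory → closed (0.004 ms⁻¹, τ = 250 ms, giving beat-to-beat
restitution). The HF "hyperphosphorylation" arm multiplies kryr⁺ by exactly
1.5 at every Ca²⁺. Luminal (JSR-load) gating is deliberately omitted; load
effects enter only through the release driving force. Consequences of that
choice are discussed under *Limitations*.

**LCC (6 states + availability).** A closed–closed–open ladder with
saturating logistic voltage rates (bounded hazards keep the fixed-step
sampler's substep count small), mirrored by a "Ca mode" with conduction
disabled; mode entry is linear in dyadic Ca²⁺ (`γ₀·ca_ds`) from every
normal-mode state and exit is a constant ω — this is the Ca²⁺-dependent
inactivation. Conduction follows a GHK flux, linear in subspace Ca²⁺,
multiplied by a deterministic Hodgkin–Huxley availability gate `y(V)`
(τ = 50 ms, 0.2% pedestal). The gate is this package's own addition: the
mirror-mode chain has no voltage-dependent inactivation, and with the small
printed K⁺ conductances the plateau otherwise never repolarizes. It plays
the role of the slow voltage-inactivation gate of classical mode-switching
LCC models.

**Stochastic integration.** Channel occupancies are integer counts per CRU.
Each time step, movers out of each state are drawn binomially with
per-channel probability `1 − exp(−q·dt)` and apportioned by conditional
binomials; the per-channel hazard per substep is capped at 0.2 and the CRU
substeps automatically when rates are high. Each CRU owns a counter-seeded
xorshift64* stream, so stream `i` is independent of `n_cru` and runs are
bitwise reproducible for a given (parameters, protocol, seed, dt). A
mean-field mode propagates expected occupancies through the same code path;
it is used for integrator-accuracy (step-halving) checks, where matching
random numbers across different step counts is not meaningful.

**Concentrations.** The dyadic Ca²⁺ balance is linear in `ca_ds` given the
channel states, so it is advanced by an exact exponential update, and the
time-averaged subspace concentration over the substep is used for all flux
bookkeeping — this keeps compartment transfers consistent and lets the
subspace relax with τ_efflux = 7 µs without stiffness. JSR (rapid
calsequestrin buffering), NSR, and myoplasm (rapid troponin + calmodulin
buffering) use explicit Euler; HH gates use Rush–Larsen. A closed-membrane
audit (sarcolemmal Ca²⁺ pathways disabled) conserves total cell Ca²⁺ to
better than 0.1% per second.

**Membrane currents.** I_K1 (instantaneous rectifier rolled off above E_K),
I_to (fast r activation, s inactivation with a small ~3% sustained
component), I_Kr (xr1 activation × inward-rectification factor), I_Ks (xs²,
slow), a minimal fast I_Na for the upstroke (disabled under voltage clamp),
NCX in the standard 3Na:1Ca exponential formulation with G_NCX = 1000 µA/µF,
a static Na⁺/K⁺ pump current and small Ca²⁺/Na⁺ backgrounds that set the
diastolic balance. Currents are µA/µF positive outward; fluxes µM/ms
positive into the receiving compartment; the µA/µF ↔ µM/ms conversion is
`C_m,tot / (2·F·V_myo)` and is unit-tested.

## Protocols and experiments

Pacing protocols are (duration, frequency) segments; a stimulus (default
−52 µA/µF, 1 ms — the narrower default keeps the delivered charge from
dominating the upstroke) fires at each segment start and then every 1/f
until the segment end, exclusive. The voltage-clamp family is fifteen 0.2 s
steps from −40 to +30 mV in 5 mV increments from a −50 mV holding
potential; the cell is conditioned by a short 1 Hz train and, by default,
every step restarts from the saved post-conditioning state (equivalent to an
arbitrarily long inter-step recovery, and much cheaper than simulating the
5 s holds, which remain available via the protocol fields). I_Na is off
under clamp.

EC-coupling gain at each test potential is peak SR release flux divided by
peak trans-sarcolemmal trigger flux, both in µM/ms referred to myoplasmic
volume; the trigger is L-type Ca²⁺ entry only (NCX-mediated entry is
excluded, matching the local-control definition of gain). A step with zero
trigger flux reports a missing value. Force is the Hill force–pCa relation
with nH = 3, pCa50 = 6 applied to the peak systolic myoplasmic Ca²⁺ (µM →
molar conversion centralized; 1 µM ↔ pCa 6); fractional release uses the
NSR concentration just before the stimulus (diastolic) and its minimum
within the beat (systolic).

## Mechanism of the transient-outward (I_to) results

The control AP carves a phase-1 notch to ≈ +10…+20 mV. In that window the
GHK driving force is several-fold larger than at the +40…+60 mV plateau, so
single LCC openings deposit large subspace Ca²⁺ footprints and ignite their
RyR clusters within milliseconds — release is notch-synchronized. Reducing
G_to by the published 67% removes the notch; openings at the resulting
higher plateau carry a much smaller driving force (ignition rate falls
roughly with the square of the footprint), so recruitment is slower and less
complete: the peak whole-cell RyR open fraction falls by ~40–60%, the peak
L-type current by ~35–50%, and the Ca²⁺ transient's time-to-peak roughly
doubles — the directions and magnitudes the acceptance suite checks.

## Spark analysis

Sparks are detected on per-CRU subspace traces by threshold (10 µM) with
hysteresis (close at 50%) and a 2 ms merge gap; systole is stimulus onset
+200 ms and events entirely outside those windows are flagged diastolic.
Census comparisons between conditions are made on the diastolic events:
during systole the detector necessarily registers the global transient as
one "event" per recruited CRU per beat in every condition, which reflects
recruitment, not spark behaviour. Spark counts and the diastolic spark rate
rise strongly in the RyR-hyperphosphorylated and full-HF arms.

## Synthetic fixtures

`fixtures.py` generates piecewise-analytic APs (exact APD90 and notch depth
by construction, raised-cosine EAD humps anchored so the planted rise equals
the nominal amplitude), double-exponential Ca²⁺ transients whose rise
constant is solved so the analytic peak time equals the requested value, and
square-pulse spark trains (fixed or Poisson placements, truth reflecting
merged geometry). They share the simulator's recording grid so detectors
see realistic quantization, and they make no attempt at biophysical realism
beyond what the metrics need — passing fixture tests validates the
*detectors*, not the biology of the simulator.

## Problem sizes

Default desk scale is 2000 CRUs (the configuration the reproduction script
uses); the test suite's stochastic suites run 256 CRUs, 6 s of pacing with
the last 3 beats analyzed, 5 seeds with ≥ 4/5 seed-majority voting for
directional claims, and shortened slow–rapid–slow segments (10/4/2 s) that
still contain the five analysis beats per segment. The full 20 000-CRU,
20 s configuration is available through the config file.

## Known limitations

* **Spark duration under RyR hyperphosphorylation.** With a point JSR and no
  luminal RyR regulation, spark termination is depletion-limited: the local
  JSR collapses in a few ms and the event outlasts it only logarithmically
  in peak amplitude. Raising kryr⁺ ×1.5 therefore lengthens sparks by only
  ~15–25%, not ~2×, unless control sparks are pushed into a sub-ignited
  regime (which makes spark peaks differ several-fold between conditions
  instead of modestly). The corresponding quantitative check is expected to
  fail and is left failing; a luminal-sensor RyR scheme would be the
  natural extension.
* Spark peak amplitudes in the hyperphosphorylated arm run ~40–70% above
  control (more simultaneous openings against a similar load), larger than
  the "modest" differences reported for the reference experiments.
* No inter-CRU diffusion: no Ca²⁺ waves, and dyadic crosstalk is only
  through bulk myoplasm.
* Fixed Na⁺ homeostasis (static pump), fixed temperature, no mechanics
  beyond the Hill force mapping.
* Early afterdepolarizations appear as plateau oscillations in the HF arms
  at slow pacing but their incidence statistics were not calibrated.
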