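# Methods

## Models

### Retinal ganglion cell (RGC)

A single-compartment membrane with six currents,

    C_m dV/dt = −I_Na − I_K − I_Ca − I_A − I_KCa − I_L + I(t),

    I_Na  = g_Na m³ h (s₁s₂) (V − V_Na)      (s₁s₂ only for tonic/phasic)
    I_K   = g_K n⁴ (V − V_K)
    I_Ca  = g_Ca c³ (V − V_Ca([Ca]_i))
    I_A   = g_A a³ b (V − V_K)
    I_KCa = g_KCa ([Ca]/K_d)² / (1 + ([Ca]/K_d)²) (V − V_K)
    I_L   = g_L (V − V_L)

Every gate obeys first-order kinetics dx/dt = α_x(V)(1−x) − β_x(V)x.
This is the only gating law consistent with an α/β rate table.  The
rate functions of ratio form k(V−V₀)/(1−exp(−(V−V₀)/10)) have a
removable singularity at V₀ and are evaluated there by their series
limit k(10 + u/2); the switch point (|u| < 10⁻⁷) keeps the branch
error far below double-precision noise.

Calcium enters through I_Ca into a thin submembrane shell of depth
r = 22 µm and relaxes to the resting level with τ_Ca = 1.5 ms:

    d[Ca]_i/dt = −5 I_Ca/(F r) − ([Ca]_i − [Ca]_res)/τ_Ca.

Unit bookkeeping: with I_Ca in µA/cm², F in C/mol and r in µm, the
quotient I_Ca/(F·r) must be multiplied by 10 to come out in mM/ms
((10⁻⁶/10⁻⁴) A·mol/(C·cm³) = 10⁻² mol/(s·cm³) = 10 mM/ms); the
factor is derived in `rgc.py` and pinned by a dimensional-analysis
unit test.  The literal prefactor 5 is part of the model definition as
implemented; related shell models use 3/(2Fr)-style geometry factors
instead, so the prefactor should be treated as empirical.  The calcium
valency is Z = 2 (Ca²⁺), giving the Nernst reversal
V_Ca = (RT/2F) ln([Ca]_e/[Ca]_i) ≈ 95.3 mV at rest.

**The s₂ closing rate is a modelling completion.**  The rate table
this model family ships with specifies α_s1, β_s1 and α_s2 but no
β_s2.  We close the system with

    β_s2(V) = k_s2 / (1 + exp(−(V+47)/4.7)),
    k_s2 = 0.0014 × (0.0008/0.00034) ≈ 0.00329 ms⁻¹,

i.e. the same logistic voltage dependence as β_s1 with its amplitude
scaled by the ratio of the two opening-rate prefactors.  With this
choice s₂,∞(V) ≡ s₁,∞(V) at every voltage and s₂ is exactly a
time-rescaled copy of s₁ (2.35× faster).  The amplitude is exposed as
`RGCParams.beta_s2_scale` so an alternative closing law can be
substituted; conclusions that depend on the slow-inactivation balance
(depolarization-block onset, phasic accommodation time) are sensitive
to it — see Limitations.

For the `repetitive` preset the sodium current omits s₁s₂; the gates
are still carried in the state (held at 1, derivatives 0) so one state
layout serves all presets.

### Morris-Lecar (ML)

    C_m dV/dt = −g_Na m∞(V)(V−V_Na) − g_K w (V−V_K) − g_L (V−V_L) + I
    dw/dt     = Φ (w∞(V) − w)/τ_w(V)

with m∞ = ½(1+tanh((V−β_m)/γ_m)), w∞ = ½(1+tanh((V−β_w)/γ_w)) and
τ_w = 1/cosh((V−β_w)/(2γ_w)), τ_w in ms and Φ applied exactly as
written (no extra frequency scaling).  β_w = 0/−13/−23 mV select
Class I/II/III; all other parameters are shared (C_m = 2 µF/cm²,
g_Na = g_K = 20, g_L = 2 mS/cm², V_Na = 50, V_K = −100, V_L = −70 mV,
β_m = −1.2, γ_m = 18, γ_w = 10 mV, Φ = 0.15).

## Stimuli

Two families, both evaluated analytically at arbitrary times (never
pre-tabulated, so RK4 stage midpoints see exact values):

* constant step of amplitude I_amp over [t_on, t_off);
* half-wave-rectified sine max(0, I_amp sin(2πf(t−t_on))), phase zero
  at onset so first-cycle latencies are comparable across frequencies.

Rectification keeps the cell from being actively hyperpolarized.
Periodic protocol durations are rounded **up** to a whole number of
periods, making spikes/cycle well defined.  Defaults: onset 50 ms;
constant steps 500 ms; periodic stimulation at least 1000 ms.

## Integration

Classic fixed-step RK4, default dt = 0.01 ms.  At this step the
stiffest gate rate in the operating range (β_c ≈ 140 ms⁻¹ near −85 mV)
gives λ·dt ≈ 1.4, well inside the RK4 stability region, and because
each gate relaxes monotonically toward a target inside [0,1] the
update cannot leave the unit interval; trajectories confirm this at
every stored sample.  A safety floor clips [Ca]_i at 10⁻⁶ mM to
protect the Nernst logarithm; it is never engaged at the default step
(asserted in tests).  Halving dt moves no spike time by more than
0.05 ms, and on a smooth subthreshold segment the global error scales
as dt⁴ (measured log-log slope 4.0 ± 0.02).  The stimulus on/off
discontinuities cost one O(dt) local error at the switching sample —
irrelevant at dt = 0.01 ms but visible to convergence studies, which
therefore measure error away from the switch points.

**Resting state.**  Simulations start from rest.  The rest finder
relaxes from V = V_L (gates at their voltage-clamp steady state,
calcium at [Ca]_res) with zero input for 1000 ms and then polishes the
endpoint with a Newton solve of the autonomous system (scipy
`optimize.root`); the polish matters because the slow s-gates have
~1 s time constants at rest and pure relaxation would still drift at
~10⁻⁶ mV/ms after one second.  The polished rest satisfies
|dV/dt| < 10⁻⁶ mV/ms; a non-quiet or inconsistent fixed point raises
an error rather than silently proceeding.

**Determinism.**  There is no randomness anywhere: identical inputs
produce bit-identical traces.  The numba-compiled kernels mirror the
pure-Python reference derivatives line for line and are pinned to them
by a test at 10⁻¹² relative tolerance.

## Spike detection and measures

A spike is an upward crossing of 0 mV (linearly interpolated between
samples) at least 2 ms after the previous spike.  Spikes in both
models overshoot 0 mV by tens of millivolts at every tested intensity,
so detection is insensitive to the threshold; both values are
configurable.  Measures: spikes/cycle (count over an integer number of
cycles), spikes/s, and first-spike latency (undefined when no spike
occurs at or after stimulus onset).  Rate windows default to the whole
stimulus — onset transients are part of the phenomenon under study — with
an option to discard initial cycles.

## Experiments

**f–I curves** use 500 ms constant steps (19 amplitudes, 0–9 µA/cm²
for RGC presets, 0–120 for ML), each from the common rest state.

**Excitability classification** follows Hodgkin's criteria,
operationalized as: Class III if no step in the sweep ever exceeds 2
spikes (onset-spiking ceiling); otherwise the onset rate is the firing
rate at the smallest amplitude with *repetitive* firing (count above
the ceiling), located by bisection to 0.002 µA/cm²; Class I if that
onset rate is below the continuity cutoff (default 10 Hz, results
stable over 5–20 Hz), Class II otherwise.  Two operational choices
matter and were validated against the ML ground truth (the three β_w
presets): (i) amplitudes producing one or two spikes are treated as
onset transients, not as the firing onset — Class II neurons have a
narrow transient band just above threshold that would otherwise
masquerade as an arbitrarily-low-rate onset; (ii) classification steps
last 1000 ms, because a 500 ms step cannot resolve rates below 6 Hz
when the relevant cutoff band starts at 5 Hz.

**Depolarization-block bounds** scan an f–I curve for the maximal
contiguous amplitude run with count ≥ 50 % of the sweep maximum (the
run containing the argmax) and for the collapsed-but-spiking
amplitudes above it.  The ratio criterion makes the result insensitive
to step duration, since numerator and maximum scale together.

**Frequency × amplitude grids** default to 5 × 3 cells per model:
2–50 Hz for the RGC presets and 5–100 Hz for ML (the ML presets are an
order of magnitude less excitable and do not respond below ~5 Hz at
any tested amplitude — Class III cells are slope detectors and never
fire under slow ramps).  The three amplitudes per model bracket that
model's firing threshold (near-threshold, intermediate, strong), which
is where the qualitative regime structure — low-pass rate maps for the
sustained-firing presets, the band-pass→low-frequency switch for the
onset-spiking pair — lives.  Full-resolution maps are rendered by
`ganglion.plotting.heatmap` as qualitative companions; the tested
surface is the coarse grid.

## Problem sizes

The shipped test and acceptance runs use: the 19-point tonic block
sweep at 500 ms; classification profiles of all six presets at 1000 ms
steps with 19- and 37-point coarse grids plus bisection; 5 × 3 grids
for six models × two measures at ≥ 1000 ms per cell.  All are chosen
as the smallest designs that resolve the phenomena they probe.

## Known limitations

* **β_s2 is not empirically constrained.**  Any behavior that hinges
  on the slow-inactivation balance inherits this uncertainty.  In
  particular, with the shipped completion the tonic preset's spike
  count rises monotonically over the 0–9 µA/cm² sweep — the 50 %
  collapse criterion finds no low-count region there (the acceptance
  script reports exactly this) — and the phasic preset's firing is
  onset-weighted only on multi-second time scales, fading after
  roughly 0.3–0.7 s of sustained drive rather than within tens of
  milliseconds.  Scans over the configurable closing-rate amplitude
  (0.0014–0.1 ms⁻¹), equal-amplitude s₁/s₂ variants and global
  slow-rate multipliers did not produce an intensity-localized block
  collapse inside the sweep, so the missing rate law is the binding
  unknown, not its amplitude.
* Consequently the repetitive and phasic presets classify as Class I
  under the shipped rate table (their sustained-firing onsets are
  continuous), while the tonic preset is Class I and all three ML
  presets recover their defining classes exactly.
* The calcium shell prefactor 5 is implemented as specified for this
  model family; alternative geometry-derived factors would change
  I_KCa's operating point (mildly — g_KCa is 0.05 mS/cm²).
* No temperature (Q10) scaling, no channel noise, no multi-compartment
  or dendritic structure, no synaptic conductances, no adaptation
  currents; stimuli are deterministic current injections only.
* Fixed-step integration only; no event-located spike times beyond
  linear interpolation at the detection threshold.
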