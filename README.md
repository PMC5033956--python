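# ganglion

Conductance-based simulation of retinal ganglion cells (RGCs) and
Morris-Lecar neurons under constant and half-wave-rectified sinusoidal
current drive, with spike-rate and first-spike-latency coding analysis.

Retinal ganglion cells are the retina's sole output neurons.
Physiologically they fall into distinct firing phenotypes — sustained
*repetitive* spiking, *tonic* firing that collapses into depolarization
block under strong drive, and *phasic* (onset-only) firing — and these
phenotypes map onto Hodgkin's three excitability classes: Class I
(continuous f–I onset, arbitrarily low firing rates), Class II
(discontinuous f–I onset) and Class III (onset spikes only).  This
package provides tested building blocks for studying how such neurons
encode periodic input into firing rate (spikes/cycle or spikes/s) and
first-spike latency, across frequency × amplitude stimulus grids.

## Models

**RGC** — a single-compartment membrane with five voltage-gated
currents and a leak:

```
C_m dV/dt = −I_Na − I_K − I_Ca − I_A − I_KCa − I_L + I(t)
```

with Hodgkin–Huxley-style gating (`dx/dt = α_x(V)(1−x) − β_x(V) x`),
an A-type potassium current `g_A a³b (V−V_K)`, a calcium-activated
potassium current with Hill-type calcium dependence, and a dynamic
calcium reversal potential `V_Ca = (RT/ZF) ln([Ca]_e/[Ca]_i)` driven by

```
d[Ca]_i/dt = −5 I_Ca/(F r) − ([Ca]_i − [Ca]_rest)/τ_Ca .
```

The three presets differ in sodium/potassium channel densities:
`repetitive` (g_Na = 50, g_K = 12 mS/cm²; sodium gating m³h), `tonic`
(200, 12) and `phasic` (120, 110), where the latter two add two slow
sodium-inactivation gates (m³h·s₁s₂).

**Morris-Lecar** — the two-variable reduction

```
C_m dV/dt = −g_Na m∞(V)(V−V_Na) − g_K w (V−V_K) − g_L (V−V_L) + I(t)
dw/dt     = Φ (w∞(V) − w)/τ_w(V)
```

whose recovery half-activation voltage β_w selects the excitability
class: 0 mV → Class I, −13 mV → Class II, −23 mV → Class III.

Both models are integrated with fixed-step classic Runge-Kutta
(RK4, default dt = 0.01 ms), the stimulus evaluated analytically at
every stage time.  Periodic drive is a half-wave-rectified sine,
`I(t) = max(0, I_amp sin(2πf t))`, so the cell is never actively
hyperpolarized; protocol durations round up to whole cycles so
spikes/cycle is always well defined.

## Worked example

```python
from ganglion import ml_preset, rgc_preset, excitability_profile, periodic_response_grid

# Hodgkin class of the Morris-Lecar beta_w = -13 mV preset
curve, call = excitability_profile(ml_preset("II"))
print(call)
# ExcitabilityCall(class_label='II', onset_amp=42.17936197916667,
#                  onset_rate_hz=46.0, max_count=203)

# Phasic RGC under rectified-sine drive: spikes per stimulus cycle
grid = periodic_response_grid(rgc_preset("phasic"), [2, 5, 10, 20, 50], [4.0, 12.0])
for amp, row in zip(grid.amps, grid.values):
    print(amp, row.round(2).tolist())
# 4.0  [0.0, 0.0, 0.2, 1.0, 0.28]
# 12.0 [23.5, 10.2, 5.0, 2.65, 1.0]
```

The classifier reports that sustained firing sets in discontinuously —
at 42.18 µA/cm² the cell jumps straight to 46 spikes/s rather than
firing arbitrarily slowly — which is the Class II signature.  The grid
rows show the phasic cell acting as a band-pass filter near threshold
(peak response at 20 Hz, silent at low frequencies) and switching to a
low-frequency preference at strong amplitude, with rate falling
monotonically in frequency.

The same functionality is exposed on the command line:

```
ganglion fi-curve --preset tonic --amps 0:9:0.5 --out runs/tonic
ganglion block-bounds --curve runs/tonic/fi_curve.csv
ganglion classify --preset ml_class3
ganglion grid --preset phasic --freqs 2,5,10,20,50 --amps 4,6,12 --out runs/ph
```

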