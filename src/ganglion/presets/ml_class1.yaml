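# Morris-Lecar, Class I excitability (continuous f-I onset).
# The three ML presets differ only in beta_w.
model: ml
class_label: I
C_m: 2.0        # uF/cm^2
g_Na: 20.0      # mS/cm^2
g_K: 20.0
g_L: 2.0
V_Na: 50.0      # mV
V_K: -100.0
V_L: -70.0
beta_m: -1.2    # mV
beta_w: 0.0     # mV
gamma_m: 18.0   # mV
gamma_w: 10.0   # mV
Phi: 0.15
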