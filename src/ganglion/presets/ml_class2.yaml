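# Morris-Lecar, Class II excitability (discontinuous f-I onset).
model: ml
class_label: II
C_m: 2.0
g_Na: 20.0
g_K: 20.0
g_L: 2.0
V_Na: 50.0
V_K: -100.0
V_L: -70.0
beta_m: -1.2
beta_w: -13.0
gamma_m: 18.0
gamma_w: 10.0
Phi: 0.15
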