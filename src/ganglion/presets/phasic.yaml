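# Phasic-firing retinal ganglion cell: slow sodium inactivation gates
# (s1, s2) combined with a large delayed-rectifier conductance confine
# spiking to the stimulus onset.
model: rgc
variant: phasic
C_m: 1.0
g_Na: 120.0
g_K: 110.0
g_Ca: 2.2
g_A: 36.0
g_KCa: 0.05
g_L: 0.05
V_Na: 35.0
V_K: -75.0
V_L: -65.0
T: 295.0
R: 8.314
F: 96485.0
Z: 2.0
r: 22.0
tau_Ca: 1.5
Ca_diss: 0.001
Ca_e: 1.8
Ca_res: 0.001
# 1/ms; s2 closing-rate amplitude: beta_s1 amplitude scaled by the
# ratio of the s2/s1 opening-rate prefactors (0.0008/0.00034), making
# s2 a time-rescaled copy of s1.
beta_s2_scale: 0.0032941176470588237
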