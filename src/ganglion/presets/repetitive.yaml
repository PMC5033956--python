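# Repetitive-spiking retinal ganglion cell: one-compartment, five
# voltage-gated channels plus leak.  The fast sodium current uses
# m^3 h gating only (no slow inactivation gates).
model: rgc
variant: repetitive
C_m: 1.0        # uF/cm^2
g_Na: 50.0      # mS/cm^2
g_K: 12.0
g_Ca: 2.2
g_A: 36.0
g_KCa: 0.05
g_L: 0.05
V_Na: 35.0      # mV
V_K: -75.0
V_L: -65.0
T: 295.0        # K
R: 8.314        # J/(mol K)
F: 96485.0      # C/mol
Z: 2.0          # valency of Ca2+
r: 22.0         # um, depth of the submembrane calcium shell
tau_Ca: 1.5     # ms
Ca_diss: 0.001  # mM
Ca_e: 1.8       # mM
Ca_res: 0.001   # mM
# 1/ms; s2 closing-rate amplitude: beta_s1 amplitude scaled by the
# ratio of the s2/s1 opening-rate prefactors (0.0008/0.00034), making
# s2 a time-rescaled copy of s1.  Unused by the repetitive variant.
beta_s2_scale: 0.0032941176470588237
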