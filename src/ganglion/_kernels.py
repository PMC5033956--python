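"""Numba-compiled inner loops for fixed-step RK4 integration.

These kernels mirror, operation for operation, the readable reference
implementations in :mod:`ganglion.rgc` and :mod:`ganglion.ml`; a test
holds the two routes together.  Parameters are packed into flat float64
arrays (layouts below) so a single compiled driver serves both models.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .rgc import CA_FLOOR, CA_UNIT_FACTOR, RGCParams
from .ml import MLParams

MODEL_RGC = 0
MODEL_ML = 1

STIM_CONSTANT = 0
STIM_RECTIFIED_SINE = 1

# RGC parameter-array layout
# 0 C_m | 1 g_Na | 2 g_K | 3 g_Ca | 4 g_A | 5 g_KCa | 6 g_L
# 7 V_Na | 8 V_K | 9 V_L | 10 RT/ZF in mV | 11 tau_Ca | 12 Ca_diss
# 13 Ca_e | 14 Ca_res | 15 calcium current factor 5*unit/(F r)
# 16 slow-gate flag | 17 beta_s2_scale


def pack_rgc_params(p: RGCParams) -> np.ndarray:
    return np.array(
        [
            p.C_m, p.g_Na, p.g_K, p.g_Ca, p.g_A, p.g_KCa, p.g_L,
            p.V_Na, p.V_K, p.V_L,
            p.nernst_prefactor_mV,
            p.tau_Ca, p.Ca_diss, p.Ca_e, p.Ca_res,
            5.0 * CA_UNIT_FACTOR / (p.F * p.r),
            1.0 if p.uses_slow_gates else 0.0,
            p.beta_s2_scale,
        ],
        dtype=np.float64,
    )


# ML parameter-array layout
# 0 C_m | 1 g_Na | 2 g_K | 3 g_L | 4 V_Na | 5 V_K | 6 V_L
# 7 beta_m | 8 beta_w | 9 gamma_m | 10 gamma_w | 11 Phi


def pack_ml_params(p: MLParams) -> np.ndarray:
    return np.array(
        [
            p.C_m, p.g_Na, p.g_K, p.g_L, p.V_Na, p.V_K, p.V_L,
            p.beta_m, p.beta_w, p.gamma_m, p.gamma_w, p.Phi,
        ],
        dtype=np.float64,
    )


@njit(cache=True)
def _ratio_rate(V, k, V0):
    # k*(V-V0)/(1 - exp(-(V-V0)/10)); series through the 0/0 point
    u = V - V0
    if abs(u) < 1e-7:
        return k * (10.0 + 0.5 * u)
    return k * u / (-math.expm1(-u / 10.0))


@njit(cache=True)
def _rgc_deriv(y, p, I, dy):
    V = y[0]
    m = y[1]; h = y[2]; s1 = y[3]; s2 = y[4]
    n = y[5]; c = y[6]; a = y[7]; b = y[8]; Ca = y[9]

    V_Ca = p[10] * math.log(p[13] / Ca)
    s12 = s1 * s2 if p[16] != 0.0 else 1.0
    I_Na = p[1] * m * m * m * h * s12 * (V - p[7])
    I_K = p[2] * n * n * n * n * (V - p[8])
    I_Ca = p[3] * c * c * c * (V - V_Ca)
    I_A = p[4] * a * a * a * b * (V - p[8])
    q = (Ca / p[12]) ** 2
    I_KCa = p[5] * (q / (1.0 + q)) * (V - p[8])
    I_L = p[6] * (V - p[9])

    dy[0] = (-(I_Na + I_K + I_Ca + I_A + I_KCa + I_L) + I) / p[0]

    am = _ratio_rate(V, 0.1, -30.0)
    bm = 4.0 * math.exp(-(V + 55.0) / 18.0)
    ah = 0.07 * math.exp(-(V + 50.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(V + 20.0) / 10.0))
    an = _ratio_rate(V, 0.02, -40.0)
    bn = 0.4 * math.exp(-(V + 50.0) / 80.0)
    ac = _ratio_rate(V, 0.3, -13.0)
    bc = 10.0 * math.exp(-(V + 38.0) / 18.0)
    aa = _ratio_rate(V, 0.006, -90.0)
    ba = 0.1 * math.exp(-(V + 30.0) / 10.0)
    ab = 0.04 * math.exp(-(V + 70.0) / 20.0)
    bb = 0.6 / (1.0 + math.exp(-(V + 40.0) / 10.0))

    dy[1] = am * (1.0 - m) - bm * m
    dy[2] = ah * (1.0 - h) - bh * h
    if p[16] != 0.0:
        as1 = 0.00034 * math.exp(-V / 63.0)
        bs1 = 0.0014 / (1.0 + math.exp(-(V + 47.0) / 4.7))
        as2 = 0.0008 * math.exp(-V / 36.0)
        bs2 = p[17] / (1.0 + math.exp(-(V + 47.0) / 4.7))
        dy[3] = as1 * (1.0 - s1) - bs1 * s1
        dy[4] = as2 * (1.0 - s2) - bs2 * s2
    else:
        dy[3] = 0.0
        dy[4] = 0.0
    dy[5] = an * (1.0 - n) - bn * n
    dy[6] = ac * (1.0 - c) - bc * c
    dy[7] = aa * (1.0 - a) - ba * a
    dy[8] = ab * (1.0 - b) - bb * b
    dy[9] = -p[15] * I_Ca - (Ca - p[14]) / p[11]


@njit(cache=True)
def _ml_deriv(y, p, I, dy):
    V = y[0]
    w = y[1]
    m_inf = 0.5 * (1.0 + math.tanh((V - p[7]) / p[9]))
    w_inf = 0.5 * (1.0 + math.tanh((V - p[8]) / p[10]))
    tau_w = 1.0 / math.cosh((V - p[8]) / (2.0 * p[10]))
    dy[0] = (
        -p[1] * m_inf * (V - p[4]) - p[2] * w * (V - p[5]) - p[3] * (V - p[6]) + I
    ) / p[0]
    dy[1] = p[11] * (w_inf - w) / tau_w


@njit(cache=True)
def _stim(kind, I_amp, omega, t_on, t_off, t):
    if t < t_on or t >= t_off:
        return 0.0
    if kind == STIM_CONSTANT:
        return I_amp
    v = I_amp * math.sin(omega * (t - t_on))
    return v if v > 0.0 else 0.0


@njit(cache=True)
def rk4_run(
    model_kind,
    y,
    p,
    dt,
    n_steps,
    stim_kind,
    I_amp,
    omega,
    t_on,
    t_off,
    V_out,
    I_out,
    Y_out,
    record_states,
):
    """Classic RK4 over n_steps from t=0, stimulus evaluated analytically
    at each stage time.  Mutates ``y`` to the final state and fills the
    output arrays (length n_steps+1).  Returns -1 on success, else the
    index of the first non-finite sample."""
    nd = y.shape[0]
    k1 = np.empty(nd)
    k2 = np.empty(nd)
    k3 = np.empty(nd)
    k4 = np.empty(nd)
    yt = np.empty(nd)

    V_out[0] = y[0]
    I_out[0] = _stim(stim_kind, I_amp, omega, t_on, t_off, 0.0)
    if record_states:
        for j in range(nd):
            Y_out[0, j] = y[j]

    for i in range(n_steps):
        t = i * dt
        Ia = _stim(stim_kind, I_amp, omega, t_on, t_off, t)
        Ib = _stim(stim_kind, I_amp, omega, t_on, t_off, t + 0.5 * dt)
        Ic = _stim(stim_kind, I_amp, omega, t_on, t_off, t + dt)

        if model_kind == MODEL_RGC:
            _rgc_deriv(y, p, Ia, k1)
            for j in range(nd):
                yt[j] = y[j] + 0.5 * dt * k1[j]
            _rgc_deriv(yt, p, Ib, k2)
            for j in range(nd):
                yt[j] = y[j] + 0.5 * dt * k2[j]
            _rgc_deriv(yt, p, Ib, k3)
            for j in range(nd):
                yt[j] = y[j] + dt * k3[j]
            _rgc_deriv(yt, p, Ic, k4)
        else:
            _ml_deriv(y, p, Ia, k1)
            for j in range(nd):
                yt[j] = y[j] + 0.5 * dt * k1[j]
            _ml_deriv(yt, p, Ib, k2)
            for j in range(nd):
                yt[j] = y[j] + 0.5 * dt * k2[j]
            _ml_deriv(yt, p, Ib, k3)
            for j in range(nd):
                yt[j] = y[j] + dt * k3[j]
            _ml_deriv(yt, p, Ic, k4)

        for j in range(nd):
            y[j] = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if model_kind == MODEL_RGC and y[9] < CA_FLOOR:
            y[9] = CA_FLOOR

        if not math.isfinite(y[0]):
            return i + 1

        V_out[i + 1] = y[0]
        I_out[i + 1] = Ic
        if record_states:
            for j in range(nd):
                Y_out[i + 1, j] = y[j]

    return -1
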