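"""One-compartment retinal ganglion cell (RGC) ionic model.

The membrane carries five voltage-gated currents — fast sodium (I_Na),
delayed-rectifier potassium (I_K), calcium (I_Ca), A-type potassium
(I_A), calcium-activated potassium (I_KCa) — plus an ohmic leak (I_L):

    C_m dV/dt = -I_Na - I_K - I_Ca - I_A - I_KCa - I_L + I

Gating variables follow first-order Hodgkin-Huxley kinetics
dx/dt = alpha_x(V)(1-x) - beta_x(V)x.  The calcium reversal potential
is the Nernst potential of the instantaneous intracellular calcium
concentration, which is itself dynamic: inward calcium current loads a
thin submembrane shell and a first-order pump relaxes it back to the
resting level.

Three named parameter presets select the firing phenotype:

``repetitive``
    g_Na = 50, g_K = 12 mS/cm^2; sodium gating is m^3 h.
``tonic``
    g_Na = 200, g_K = 12 mS/cm^2; sodium gating is m^3 h s1 s2, where
    s1 and s2 are slow inactivation gates.  Fires tonically at moderate
    drive and enters depolarization block at high drive.
``phasic``
    g_Na = 120, g_K = 110 mS/cm^2, same slow-gated sodium current;
    spikes only at stimulus onset.

Internal unit system: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2, mM, um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GATES",
    "STATE_VARS",
    "RGCParams",
    "RGCState",
    "CurrentBreakdown",
    "rgc_preset",
    "rate_constants",
    "steady_state_gate",
    "calcium_reversal",
    "membrane_currents",
    "rgc_derivatives",
]

#: Gating variables, in state-vector order.
GATES = ("m", "h", "s1", "s2", "n", "c", "a", "b")

#: Full state layout used throughout the package.
STATE_VARS = ("V",) + GATES + ("Ca_i",)

#: Default amplitude (1/ms) of the s2 closing rate.  The model
#: family's rate table gives only the opening rate alpha_s2; the
#: closing rate is modelled here with the same logistic voltage
#: dependence as beta_s1, its amplitude scaled by the ratio of the two
#: opening-rate prefactors (0.0008/0.00034).  With that choice
#: s2_inf(V) = s1_inf(V) at every voltage and s2 is simply a
#: time-rescaled copy of s1.  The amplitude is configurable
#: (``RGCParams.beta_s2_scale``) so an alternative closing law can be
#: substituted.
BETA_S2_SCALE_DEFAULT = 0.0014 * 0.0008 / 0.00034

#: Lowest intracellular calcium (mM) the integrator will report; guards
#: the Nernst logarithm.  Never reached in normal operating regimes.
CA_FLOOR = 1e-6

# Unit conversion for the calcium balance -5 I_Ca / (F r):
#   I_Ca [uA/cm^2] = 1e-6 C/(s cm^2),  r [um] = 1e-4 cm
#   => I_Ca/(F r) = 1e-2 / (F[C/mol]) mol/(s cm^3) per unit value
#   1 mol/(s cm^3) = 1e6 mM / 1e3 ms = 1e3 mM/ms
#   => multiply the raw value by 1e-2 * 1e3 = 10 to obtain mM/ms.
CA_UNIT_FACTOR = 10.0

_VARIANTS = ("repetitive", "tonic", "phasic")


@dataclass(frozen=True)
class RGCParams:
    """Immutable RGC parameter bundle.

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2,
    concentrations in mM, shell depth ``r`` in um, ``tau_Ca`` in ms.
    ``variant`` selects the sodium-gating scheme: the slow inactivation
    gates s1, s2 act only for ``tonic`` and ``phasic``.
    """

    variant: str
    C_m: float = 1.0
    g_Na: float = 50.0
    g_K: float = 12.0
    g_Ca: float = 2.2
    g_A: float = 36.0
    g_KCa: float = 0.05
    g_L: float = 0.05
    V_Na: float = 35.0
    V_K: float = -75.0
    V_L: float = -65.0
    T: float = 295.0
    R: float = 8.314
    F: float = 96485.0
    Z: float = 2.0
    r: float = 22.0
    tau_Ca: float = 1.5
    Ca_diss: float = 0.001
    Ca_e: float = 1.8
    Ca_res: float = 0.001
    beta_s2_scale: float = BETA_S2_SCALE_DEFAULT

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {_VARIANTS}"
            )
        for name in ("g_Na", "g_K", "g_Ca", "g_A", "g_KCa", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("C_m", "tau_Ca", "Ca_diss", "Ca_e", "Ca_res", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def uses_slow_gates(self) -> bool:
        return self.variant != "repetitive"

    @property
    def nernst_prefactor_mV(self) -> float:
        """RT/ZF in millivolts."""
        return 1000.0 * self.R * self.T / (self.Z * self.F)

    def with_(self, **kwargs) -> "RGCParams":
        return replace(self, **kwargs)


@dataclass
class RGCState:
    """Instantaneous dynamical state: V (mV), eight gates, Ca_i (mM)."""

    V: float
    m: float
    h: float
    s1: float
    s2: float
    n: float
    c: float
    a: float
    b: float
    Ca_i: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "RGCState":
        return cls(*(float(v) for v in np.asarray(y, dtype=float)))

    def validate(self) -> None:
        for g in GATES:
            x = getattr(self, g)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {g}={x} outside [0, 1]")
        if not self.Ca_i > 0:
            raise ValueError(f"Ca_i={self.Ca_i} must be > 0")


@dataclass(frozen=True)
class CurrentBreakdown:
    """Per-channel membrane current densities, uA/cm^2 (outward > 0)."""

    I_Na: float
    I_K: float
    I_Ca: float
    I_A: float
    I_KCa: float
    I_L: float

    @property
    def total(self) -> float:
        return self.I_Na + self.I_K + self.I_Ca + self.I_A + self.I_KCa + self.I_L


def _preset_path(name: str):
    from importlib.resources import files

    return files("ganglion.presets").joinpath(f"{name}.yaml")


def rgc_preset(name: str) -> RGCParams:
    """Load one of the named presets: repetitive, tonic or phasic."""
    import yaml

    if name not in _VARIANTS:
        raise ValueError(f"unknown RGC preset {name!r}; expected one of {_VARIANTS}")
    raw = yaml.safe_load(_preset_path(name).read_text())
    raw.pop("model", None)
    return RGCParams(**raw)


def _ratio_rate(V: float, k: float, V0: float, sigma: float = 10.0) -> float:
    """Evaluate k (V - V0) / (1 - exp(-(V - V0)/sigma)).

    The expression has a removable singularity at V = V0 with limit
    k * sigma; near it we use the series u/(1-e^(-u/s)) = s + u/2 + ...
    """
    u = V - V0
    if abs(u) < 1e-7:
        return k * (sigma + 0.5 * u)
    return k * u / (-math.expm1(-u / sigma))


def _logistic(V: float, amp: float, V_half: float, sigma: float) -> float:
    """amp / (1 + exp(-(V - V_half)/sigma))."""
    return amp / (1.0 + math.exp(-(V - V_half) / sigma))


def rate_constants(
    V: float, gate: str, beta_s2_scale: float = BETA_S2_SCALE_DEFAULT
) -> tuple[float, float]:
    """Voltage-dependent opening/closing rates (alpha, beta) in 1/ms.

    Ratio-form rates are continuous through their removable
    singularities.  ``beta_s2_scale`` sets the amplitude of the
    modelled s2 closing rate (see module notes).
    """
    if not (isinstance(V, (int, float)) and math.isfinite(V)):
        raise ValueError(f"V must be a finite number, got {V!r}")
    if gate == "m":
        return _ratio_rate(V, 0.1, -30.0), 4.0 * math.exp(-(V + 55.0) / 18.0)
    if gate == "h":
        return 0.07 * math.exp(-(V + 50.0) / 20.0), _logistic(V, 1.0, -20.0, 10.0)
    if gate == "s1":
        return 0.00034 * math.exp(-V / 63.0), _logistic(V, 0.0014, -47.0, 4.7)
    if gate == "s2":
        return 0.0008 * math.exp(-V / 36.0), _logistic(V, beta_s2_scale, -47.0, 4.7)
    if gate == "n":
        return _ratio_rate(V, 0.02, -40.0), 0.4 * math.exp(-(V + 50.0) / 80.0)
    if gate == "c":
        return _ratio_rate(V, 0.3, -13.0), 10.0 * math.exp(-(V + 38.0) / 18.0)
    if gate == "a":
        return _ratio_rate(V, 0.006, -90.0), 0.1 * math.exp(-(V + 30.0) / 10.0)
    if gate == "b":
        return 0.04 * math.exp(-(V + 70.0) / 20.0), _logistic(V, 0.6, -40.0, 10.0)
    raise ValueError(f"unknown gate {gate!r}; expected one of {GATES}")


def steady_state_gate(
    V: float, gate: str, beta_s2_scale: float = BETA_S2_SCALE_DEFAULT
) -> float:
    """Steady-state activation alpha/(alpha+beta) at clamped voltage."""
    alpha, beta = rate_constants(V, gate, beta_s2_scale)
    denom = alpha + beta
    if denom <= 0.0:
        raise ZeroDivisionError(f"degenerate kinetics for gate {gate} at V={V} mV")
    return alpha / denom


def calcium_reversal(Ca_i: float, params: RGCParams) -> float:
    """Nernst reversal potential (mV) of calcium at concentration Ca_i.

    V_Ca = (RT/ZF) ln([Ca]_e / [Ca]_i), expressed in millivolts.
    """
    if Ca_i <= 0:
        raise ValueError(f"Ca_i must be > 0, got {Ca_i}")
    return params.nernst_prefactor_mV * math.log(params.Ca_e / Ca_i)


def membrane_currents(state: RGCState, params: RGCParams) -> CurrentBreakdown:
    """Evaluate the six membrane current densities at the given state."""
    V = state.V
    s12 = state.s1 * state.s2 if params.uses_slow_gates else 1.0
    I_Na = params.g_Na * state.m**3 * state.h * s12 * (V - params.V_Na)
    I_K = params.g_K * state.n**4 * (V - params.V_K)
    I_Ca = params.g_Ca * state.c**3 * (V - calcium_reversal(state.Ca_i, params))
    I_A = params.g_A * state.a**3 * state.b * (V - params.V_K)
    ca_ratio_sq = (state.Ca_i / params.Ca_diss) ** 2
    I_KCa = params.g_KCa * (ca_ratio_sq / (1.0 + ca_ratio_sq)) * (V - params.V_K)
    I_L = params.g_L * (V - params.V_L)
    return CurrentBreakdown(I_Na, I_K, I_Ca, I_A, I_KCa, I_L)


def rgc_derivatives(state: RGCState, params: RGCParams, I: float) -> np.ndarray:
    """Time derivatives of the ten state variables (order: STATE_VARS).

    dV/dt = (-sum of ionic currents + I) / C_m; gates follow first-order
    kinetics; calcium obeys dCa/dt = -5 I_Ca/(F r) - (Ca - Ca_res)/tau_Ca
    with the mM/ms unit factor derived in this module's constants.
    For the ``repetitive`` variant the s1, s2 gates are carried in the
    state but frozen at their values (derivative 0).
    """
    cur = membrane_currents(state, params)
    out = np.empty(len(STATE_VARS))
    out[0] = (-cur.total + I) / params.C_m
    for i, g in enumerate(GATES, start=1):
        if g in ("s1", "s2") and not params.uses_slow_gates:
            out[i] = 0.0
            continue
        alpha, beta = rate_constants(state.V, g, params.beta_s2_scale)
        x = getattr(state, g)
        out[i] = alpha * (1.0 - x) - beta * x
    out[9] = (
        -5.0 * CA_UNIT_FACTOR * cur.I_Ca / (params.F * params.r)
        - (state.Ca_i - params.Ca_res) / params.tau_Ca
    )
    return out


def initial_state(params: RGCParams, V: float | None = None) -> RGCState:
    """Construct a cold-start state: clamped gates at steady state,
    calcium at rest.  Used to seed the rest-finding relaxation."""
    V0 = params.V_L if V is None else V
    gates = {g: steady_state_gate(V0, g, params.beta_s2_scale) for g in GATES}
    if not params.uses_slow_gates:
        gates["s1"] = 1.0
        gates["s2"] = 1.0
    return RGCState(V=V0, Ca_i=params.Ca_res, **gates)
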