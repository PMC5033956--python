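"""Fixed-step fourth-order Runge-Kutta integration of either model.

The solver is deliberately plain: classic RK4 with a fixed step
(default 0.01 ms), the stimulus evaluated analytically at every stage
time.  Simulations start from the model's resting state, located by
relaxing the system with zero input and polishing the endpoint with a
root solve of the autonomous vector field.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels as K
from .forcing import StimulusProtocol
from .ml import MLParams, MLState, ml_derivatives, ml_steady_states
from .ml import initial_state as ml_initial_state
from .rgc import (
    GATES,
    RGCParams,
    RGCState,
    rgc_derivatives,
    steady_state_gate,
)
from .rgc import initial_state as rgc_initial_state

__all__ = [
    "Trace",
    "IntegrationError",
    "RestNotConvergedError",
    "DEFAULT_DT",
    "find_rest",
    "simulate",
    "model_id",
]

DEFAULT_DT = 0.01  # ms
DRIFT_TOL = 1e-6  # mV/ms residual allowed at rest


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""

    def __init__(self, t_fail: float):
        super().__init__(f"integration blew up at t = {t_fail:.4f} ms")
        self.t_fail = t_fail


class RestNotConvergedError(RuntimeError):
    """Relaxation did not settle to a quiescent fixed point (the rest
    state may be oscillatory)."""


def model_id(params: RGCParams | MLParams) -> str:
    if isinstance(params, RGCParams):
        return f"rgc:{params.variant}"
    return f"ml:{params.class_label}"


@dataclass
class Trace:
    """Uniformly sampled record of one simulation.

    ``V`` holds the membrane potential at every step (full dt
    resolution, as required by spike detection); ``states`` optionally
    holds the complete state matrix (n_samples x n_vars).
    """

    times: np.ndarray
    V: np.ndarray
    applied_current: np.ndarray
    dt: float
    model_id: str
    protocol: StimulusProtocol
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.V) != len(self.times):
            raise ValueError("V and times must have equal length")

    @property
    def t_total(self) -> float:
        return float(self.times[-1])

    def check_invariants(self) -> None:
        """Assert physical-state invariants at every stored sample:
        gates and w in [0, 1], calcium strictly positive and above the
        numerical floor."""
        if self.states is None:
            raise ValueError("trace was recorded without full states")
        if self.model_id.startswith("rgc"):
            gates = self.states[:, 1:9]
            if gates.min() < 0.0 or gates.max() > 1.0:
                raise AssertionError("gating variable left [0, 1]")
            ca = self.states[:, 9]
            if ca.min() <= 0.0:
                raise AssertionError("calcium concentration not positive")
        else:
            w = self.states[:, 1]
            if w.min() < 0.0 or w.max() > 1.0:
                raise AssertionError("recovery variable left [0, 1]")


def _rest_residual_rgc(x: np.ndarray, params: RGCParams) -> np.ndarray:
    V, Ca = x
    gates = {g: steady_state_gate(V, g, params.beta_s2_scale) for g in GATES}
    if not params.uses_slow_gates:
        gates["s1"] = gates["s2"] = 1.0
    state = RGCState(V=V, Ca_i=max(Ca, 1e-9), **gates)
    d = rgc_derivatives(state, params, 0.0)
    return np.array([d[0], d[9] * 1e3])  # scale Ca residual toward mV/ms magnitude


def _rest_residual_ml(x: np.ndarray, params: MLParams) -> list[float]:
    V = float(x[0])
    _, w_inf, _ = ml_steady_states(V, params)
    dV, _ = ml_derivatives(MLState(V=V, w=w_inf), params, 0.0)
    return [dV]


def _relax(params, y0: np.ndarray, settle: float, dt: float) -> np.ndarray:
    n = int(round(settle / dt))
    V_out = np.empty(n + 1)
    I_out = np.empty(n + 1)
    y = y0.copy()
    if isinstance(params, RGCParams):
        status = K.rk4_run(
            K.MODEL_RGC, y, K.pack_rgc_params(params), dt, n,
            K.STIM_CONSTANT, 0.0, 0.0, settle + 1.0, settle + 2.0,
            V_out, I_out, np.empty((1, 1)), False,
        )
    else:
        status = K.rk4_run(
            K.MODEL_ML, y, K.pack_ml_params(params), dt, n,
            K.STIM_CONSTANT, 0.0, 0.0, settle + 1.0, settle + 2.0,
            V_out, I_out, np.empty((1, 1)), False,
        )
    if status >= 0:
        raise IntegrationError(status * dt)
    return y


@lru_cache(maxsize=64)
def find_rest(
    params: RGCParams | MLParams,
    settle: float = 1000.0,
    dt: float = DEFAULT_DT,
    drift_tol: float = DRIFT_TOL,
) -> RGCState | MLState:
    """Locate the quiescent resting state of a model.

    Relaxes from V = V_L (gates at voltage-clamp steady state, calcium
    at its resting level) with zero input for ``settle`` ms, then
    polishes the endpoint with a root solve of the autonomous system.
    Raises :class:`RestNotConvergedError` when the polished fixed point
    is not quiet or not consistent with the relaxation endpoint.
    """
    from scipy.optimize import root

    if isinstance(params, RGCParams):
        y = _relax(params, rgc_initial_state(params).as_array(), settle, dt)
        sol = root(_rest_residual_rgc, x0=[y[0], y[9]], args=(params,), tol=1e-12)
        V_eq, Ca_eq = sol.x
        if not sol.success or abs(V_eq - y[0]) > 2.0:
            raise RestNotConvergedError(
                f"rest polish failed for {model_id(params)}: {sol.message}"
            )
        gates = {g: steady_state_gate(V_eq, g, params.beta_s2_scale) for g in GATES}
        if not params.uses_slow_gates:
            gates["s1"] = gates["s2"] = 1.0
        rest = RGCState(V=float(V_eq), Ca_i=float(Ca_eq), **gates)
        resid = rgc_derivatives(rest, params, 0.0)[0]
    else:
        y = _relax(params, ml_initial_state(params).as_array(), settle, dt)
        sol = root(_rest_residual_ml, x0=[y[0]], args=(params,), tol=1e-12)
        V_eq = float(sol.x[0])
        if not sol.success or abs(V_eq - y[0]) > 2.0:
            raise RestNotConvergedError(
                f"rest polish failed for {model_id(params)}: {sol.message}"
            )
        _, w_inf, _ = ml_steady_states(V_eq, params)
        rest = MLState(V=V_eq, w=w_inf)
        resid = ml_derivatives(rest, params, 0.0)[0]
    if abs(resid) > drift_tol:
        raise RestNotConvergedError(
            f"resting drift |dV/dt| = {abs(resid):.2e} mV/ms exceeds {drift_tol:g}"
        )
    return rest


def simulate(
    params: RGCParams | MLParams,
    protocol: StimulusProtocol,
    dt: float = DEFAULT_DT,
    initial: RGCState | MLState | None = None,
    record_states: bool = False,
) -> Trace:
    """Integrate a model under a stimulus protocol with RK4.

    Starts from the relaxed resting state unless ``initial`` is given.
    Returns the full-resolution trace; raises
    :class:`IntegrationError` if the state becomes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if isinstance(params, RGCParams):
        kind, pack, nd = K.MODEL_RGC, K.pack_rgc_params(params), 10
    elif isinstance(params, MLParams):
        kind, pack, nd = K.MODEL_ML, K.pack_ml_params(params), 2
    else:
        raise TypeError(f"unsupported params type {type(params)!r}")

    y = (initial if initial is not None else find_rest(params, dt=dt)).as_array()
    n = int(round(protocol.t_total / dt))
    V_out = np.empty(n + 1)
    I_out = np.empty(n + 1)
    Y_out = np.empty((n + 1, nd)) if record_states else np.empty((1, 1))

    stim_kind = K.STIM_CONSTANT if protocol.kind == "constant" else K.STIM_RECTIFIED_SINE
    omega = 0.0 if protocol.f is None else 2.0 * np.pi * protocol.f / 1000.0
    status = K.rk4_run(
        kind, y, pack, dt, n, stim_kind, protocol.I_amp, omega,
        protocol.t_on, protocol.t_off, V_out, I_out, Y_out, record_states,
    )
    if status >= 0:
        raise IntegrationError(status * dt)

    return Trace(
        times=np.arange(n + 1) * dt,
        V=V_out,
        applied_current=I_out,
        dt=dt,
        model_id=model_id(params),
        protocol=protocol,
        states=Y_out if record_states else None,
    )
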