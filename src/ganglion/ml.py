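"""Two-variable Morris-Lecar (ML) model with the three Hodgkin
excitability classes.

    C_m dV/dt = -g_Na m_inf(V)(V - V_Na) - g_K w (V - V_K)
                - g_L (V - V_L) + I
    dw/dt     = Phi (w_inf(V) - w) / tau_w(V)

with instantaneous fast activation m_inf = 0.5(1 + tanh((V-beta_m)/gamma_m)),
recovery target w_inf = 0.5(1 + tanh((V-beta_w)/gamma_w)) and recovery
time scale tau_w = 1/cosh((V-beta_w)/(2 gamma_w)) (ms).

The half-activation voltage of the recovery variable selects the
excitability class: beta_w = 0 mV gives Class I (continuous f-I onset),
-13 mV gives Class II (discontinuous onset), -23 mV gives Class III
(onset spiking only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MLParams",
    "MLState",
    "ml_preset",
    "ml_steady_states",
    "ml_derivatives",
]

_CLASS_LABELS = ("I", "II", "III")
_PRESET_FILES = {"I": "ml_class1", "II": "ml_class2", "III": "ml_class3"}


@dataclass(frozen=True)
class MLParams:
    """Morris-Lecar parameters (mS/cm^2, mV, uF/cm^2; Phi dimensionless)."""

    class_label: str
    C_m: float = 2.0
    g_Na: float = 20.0
    g_K: float = 20.0
    g_L: float = 2.0
    V_Na: float = 50.0
    V_K: float = -100.0
    V_L: float = -70.0
    beta_m: float = -1.2
    beta_w: float = 0.0
    gamma_m: float = 18.0
    gamma_w: float = 10.0
    Phi: float = 0.15

    def __post_init__(self) -> None:
        if self.class_label not in _CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {_CLASS_LABELS}, got {self.class_label!r}"
            )
        if self.gamma_m <= 0 or self.gamma_w <= 0 or self.Phi <= 0:
            raise ValueError("gamma_m, gamma_w and Phi must be > 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")

    def with_(self, **kwargs) -> "MLParams":
        return replace(self, **kwargs)


@dataclass
class MLState:
    """Membrane potential V (mV) and recovery variable w in [0, 1]."""

    V: float
    w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.w], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MLState":
        V, w = np.asarray(y, dtype=float)
        return cls(float(V), float(w))

    def validate(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w={self.w} outside [0, 1]")


def ml_preset(name: str) -> MLParams:
    """Load a class preset by label ('I', 'II', 'III') or file stem
    ('ml_class1', ...)."""
    import yaml
    from importlib.resources import files

    stem = _PRESET_FILES.get(name, name)
    if stem not in _PRESET_FILES.values():
        raise ValueError(
            f"unknown ML preset {name!r}; expected one of "
            f"{sorted(_CLASS_LABELS) + sorted(_PRESET_FILES.values())}"
        )
    raw = yaml.safe_load(files("ganglion.presets").joinpath(f"{stem}.yaml").read_text())
    raw.pop("model", None)
    return MLParams(**raw)


def ml_steady_states(V: float, params: MLParams) -> tuple[float, float, float]:
    """(m_inf, w_inf, tau_w) at clamped voltage V; tau_w in ms."""
    m_inf = 0.5 * (1.0 + math.tanh((V - params.beta_m) / params.gamma_m))
    w_inf = 0.5 * (1.0 + math.tanh((V - params.beta_w) / params.gamma_w))
    tau_w = 1.0 / math.cosh((V - params.beta_w) / (2.0 * params.gamma_w))
    return m_inf, w_inf, tau_w


def ml_derivatives(state: MLState, params: MLParams, I: float) -> tuple[float, float]:
    """(dV/dt, dw/dt) in mV/ms and 1/ms."""
    m_inf, w_inf, tau_w = ml_steady_states(state.V, params)
    dV = (
        -params.g_Na * m_inf * (state.V - params.V_Na)
        - params.g_K * state.w * (state.V - params.V_K)
        - params.g_L * (state.V - params.V_L)
        + I
    ) / params.C_m
    dw = params.Phi * (w_inf - state.w) / tau_w
    return dV, dw


def initial_state(params: MLParams, V: float | None = None) -> MLState:
    """Cold-start state at V (default V_L) with w at its steady state."""
    V0 = params.V_L if V is None else V
    _, w_inf, _ = ml_steady_states(V0, params)
    return MLState(V=V0, w=w_inf)
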