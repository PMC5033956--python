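"""Stimulus waveforms: constant steps and half-wave-rectified sines.

Two stimulus families drive every experiment in this package:

* ``constant`` — a current step of amplitude ``I_amp`` over
  [t_on, t_off).
* ``rectified_sine`` — I(t) = max(0, I_amp sin(2 pi f (t - t_on)))
  over the same window; the negative lobes are clipped to zero so the
  cell is never actively hyperpolarized.  Phase is zero at onset
  (the stimulus starts on the rising zero-crossing), which makes
  first-cycle latencies comparable across frequencies.

Frequencies are given in Hz and converted internally to the ms time
base.  The waveform is evaluated analytically at arbitrary times (in
particular at Runge-Kutta stage midpoints), never pre-tabulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

__all__ = [
    "StimulusProtocol",
    "StimulusTiming",
    "stimulus_value",
    "cycles_in",
    "build_protocol_grid",
]

_KINDS = ("constant", "rectified_sine")


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative description of one forcing waveform.

    ``I_amp`` in uA/cm^2, ``f`` in Hz (rectified_sine only), times in ms.
    Outside [t_on, t_off) the delivered current is zero; the simulation
    runs to ``t_total``.
    """

    kind: str
    I_amp: float
    t_on: float
    t_off: float
    t_total: float
    f: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.I_amp < 0:
            raise ValueError("I_amp must be >= 0")
        if not 0.0 <= self.t_on < self.t_off <= self.t_total:
            raise ValueError(
                f"need 0 <= t_on < t_off <= t_total, got "
                f"({self.t_on}, {self.t_off}, {self.t_total})"
            )
        if self.kind == "rectified_sine":
            if self.f is None or self.f <= 0:
                raise ValueError("rectified_sine requires f > 0")
        elif self.f is not None:
            raise ValueError("constant stimulus takes no frequency")

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on

    @property
    def period_ms(self) -> float | None:
        return None if self.f is None else 1000.0 / self.f

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StimulusTiming:
    """Shared timing for a protocol sweep: onset, requested stimulus
    duration and post-stimulus tail, all in ms.  For periodic stimuli
    the duration is extended to a whole number of cycles."""

    t_on: float = 50.0
    duration: float = 1000.0
    tail: float = 0.0

    def __post_init__(self) -> None:
        if self.t_on < 0 or self.duration <= 0 or self.tail < 0:
            raise ValueError("need t_on >= 0, duration > 0, tail >= 0")


def constant_step(
    I_amp: float, timing: StimulusTiming = StimulusTiming(duration=500.0)
) -> StimulusProtocol:
    """Convenience constructor for a constant current step."""
    t_off = timing.t_on + timing.duration
    return StimulusProtocol(
        kind="constant",
        I_amp=I_amp,
        t_on=timing.t_on,
        t_off=t_off,
        t_total=t_off + timing.tail,
    )


def rectified_sine(
    I_amp: float, f: float, timing: StimulusTiming = StimulusTiming()
) -> StimulusProtocol:
    """Half-wave-rectified sine protocol with a whole number of cycles.

    The requested duration is rounded *up* to the next integer number
    of periods so that spikes/cycle is well defined.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    period = 1000.0 / f
    n_cycles = max(1, math.ceil(timing.duration / period - 1e-9))
    t_off = timing.t_on + n_cycles * period
    return StimulusProtocol(
        kind="rectified_sine",
        I_amp=I_amp,
        f=f,
        t_on=timing.t_on,
        t_off=t_off,
        t_total=t_off + timing.tail,
    )


def stimulus_value(protocol: StimulusProtocol, t: float) -> float:
    """Delivered current density (uA/cm^2) at time t (ms)."""
    if not 0.0 <= t <= protocol.t_total:
        raise ValueError(f"t={t} outside [0, {protocol.t_total}]")
    if not protocol.t_on <= t < protocol.t_off:
        return 0.0
    if protocol.kind == "constant":
        return protocol.I_amp
    omega = 2.0 * math.pi * protocol.f / 1000.0  # rad/ms
    return max(0.0, protocol.I_amp * math.sin(omega * (t - protocol.t_on)))


def cycles_in(protocol: StimulusProtocol, window: tuple[float, float] | None = None) -> float:
    """Number of stimulus periods spanned by the window (default: the
    full stimulus window)."""
    if protocol.f is None:
        raise ValueError("cycle count requires a periodic protocol")
    lo, hi = window if window is not None else (protocol.t_on, protocol.t_off)
    return (hi - lo) * protocol.f / 1000.0


def build_protocol_grid(
    f_values: Sequence[float],
    amp_values: Sequence[float],
    timing: StimulusTiming = StimulusTiming(),
) -> list[StimulusProtocol]:
    """Cartesian product of frequencies x amplitudes as rectified-sine
    protocols, row-major in amplitude then frequency (the amplitude is
    the slow axis).  Every protocol shares ``timing``; each duration is
    rounded up to a whole number of its own cycles."""
    f_values = list(f_values)
    amp_values = list(amp_values)
    if not f_values or not amp_values:
        raise ValueError("frequency and amplitude axes must be non-empty")
    if any(f <= 0 for f in f_values):
        raise ValueError("frequencies must be positive")
    if any(a < 0 for a in amp_values):
        raise ValueError("amplitudes must be non-negative")
    return [
        rectified_sine(amp, f, timing) for amp in amp_values for f in f_values
    ]
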