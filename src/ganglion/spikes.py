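"""Spike detection and the two coding measures.

A spike is an upward crossing of a voltage threshold (default 0 mV —
action potentials in both models overshoot it by tens of mV, so the
exact value is uncritical), debounced by a refractory window (default
2 ms).  Crossing times are linearly interpolated between the bracketing
samples.

Two measures summarize a response to a stimulus:

* firing rate, as spikes/cycle for periodic stimuli (count divided by
  the number of complete cycles) or spikes/second for any window;
* first-spike latency, the delay from stimulus onset to the first
  spike, undefined when the cell never responds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forcing import StimulusProtocol, cycles_in
from .integrate import Trace

__all__ = [
    "SpikeTrain",
    "CodingMeasure",
    "DEFAULT_THRESHOLD",
    "DEFAULT_REFRACTORY",
    "detect_spikes",
    "spikes_per_cycle",
    "spikes_per_second",
    "first_spike_latency",
]

DEFAULT_THRESHOLD = 0.0  # mV
DEFAULT_REFRACTORY = 2.0  # ms


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times (ms, strictly increasing)."""

    times: np.ndarray
    threshold: float
    refractory: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.times)

    def count(self, window: tuple[float, float] | None = None) -> int:
        if window is None:
            return len(self.times)
        lo, hi = window
        return int(np.count_nonzero((self.times >= lo) & (self.times < hi)))


@dataclass(frozen=True)
class CodingMeasure:
    """One scalar response measure; ``defined`` is False (and ``value``
    NaN) when the measure does not exist, e.g. latency with no spike."""

    kind: str
    value: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined != (not math.isnan(self.value)):
            raise ValueError("value must be NaN exactly when undefined")

    @classmethod
    def undefined(cls, kind: str) -> "CodingMeasure":
        return cls(kind=kind, value=float("nan"), defined=False)


def detect_spikes(
    trace: Trace,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> SpikeTrain:
    """Threshold-crossing spike detection on the full-resolution trace.

    A candidate is every sample pair with V[i] < threshold <= V[i+1];
    candidates closer than ``refractory`` ms to the last accepted spike
    are discarded.
    """
    V = trace.V
    t = trace.times
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    times: list[float] = []
    for i in idx:
        frac = (threshold - V[i]) / (V[i + 1] - V[i])
        tc = t[i] + frac * trace.dt
        if not times or tc - times[-1] >= refractory:
            times.append(float(tc))
    return SpikeTrain(
        times=np.asarray(times),
        threshold=threshold,
        refractory=refractory,
        source=trace.model_id,
    )


def _integer_cycles(protocol: StimulusProtocol, window: tuple[float, float]) -> int:
    n = cycles_in(protocol, window)
    if abs(n - round(n)) > 1e-6 or round(n) < 1:
        raise ValueError(
            f"analysis window {window} spans {n:.6f} cycles; "
            "an integer number of complete cycles is required"
        )
    return int(round(n))


def spikes_per_cycle(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    window: tuple[float, float] | None = None,
) -> CodingMeasure:
    """Spike count divided by the number of complete stimulus cycles in
    the window (default: the whole stimulus).  Always defined; an empty
    train gives 0."""
    if protocol.kind != "rectified_sine":
        raise ValueError("spikes/cycle requires a periodic protocol")
    win = window if window is not None else (protocol.t_on, protocol.t_off)
    n_cycles = _integer_cycles(protocol, win)
    return CodingMeasure("spikes_per_cycle", train.count(win) / n_cycles)


def spikes_per_second(
    train: SpikeTrain, window: tuple[float, float]
) -> CodingMeasure:
    """Spike count divided by window length, in Hz."""
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty analysis window ({lo}, {hi})")
    return CodingMeasure("spikes_per_second", train.count(window) / ((hi - lo) / 1000.0))


def first_spike_latency(train: SpikeTrain, t_on: float) -> CodingMeasure:
    """Delay (ms) from stimulus onset to the first spike at or after it;
    undefined when no such spike exists."""
    after = train.times[train.times >= t_on]
    if len(after) == 0:
        return CodingMeasure.undefined("first_spike_latency")
    return CodingMeasure("first_spike_latency", float(after[0] - t_on))
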