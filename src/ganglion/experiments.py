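"""Experiment layer: intensity sweeps, frequency x amplitude grids,
Hodgkin excitability classification and depolarization-block bounds.

Every experiment starts each simulation from the model's relaxed
resting state, so sweep cells are independent and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcing import StimulusTiming, constant_step, rectified_sine
from .integrate import DEFAULT_DT, IntegrationError, model_id, simulate
from .ml import MLParams
from .rgc import RGCParams
from .spikes import (
    DEFAULT_REFRACTORY,
    DEFAULT_THRESHOLD,
    detect_spikes,
    first_spike_latency,
    spikes_per_cycle,
    spikes_per_second,
)

__all__ = [
    "SweepResult",
    "ExcitabilityCall",
    "BlockBounds",
    "UnclassifiableError",
    "BlockNotApplicableError",
    "fI_curve",
    "latency_curve",
    "periodic_response_cell",
    "periodic_response_grid",
    "classify_excitability",
    "excitability_profile",
    "depolarization_block_bounds",
    "freq_preference",
]

STEP_TIMING = StimulusTiming(t_on=50.0, duration=500.0, tail=0.0)
GRID_TIMING = StimulusTiming(t_on=50.0, duration=1000.0, tail=0.0)

#: Maximum spikes per constant step still counted as onset-only
#: (Class III) firing.
SINGLE_SPIKE_CEILING = 2

#: Onset firing rate (Hz) below which an f-I curve counts as continuous
#: (Class I).  Hodgkin's criterion is qualitative; this operationalizes
#: "arbitrarily low firing rates" on a finite grid.
CONTINUITY_CUTOFF_HZ = 10.0


class UnclassifiableError(ValueError):
    """The f-I curve contains no spiking amplitude."""


class BlockNotApplicableError(ValueError):
    """No spiking anywhere in the sweep; block bounds undefined."""


@dataclass
class SweepResult:
    """Measure values over an intensity sweep (1-D) or a frequency x
    amplitude grid (2-D, shaped (n_amp, n_freq); amplitude is the slow
    axis).  ``defined`` is False where the measure does not exist
    (no-response cells, the white areas of latency maps)."""

    model_id: str
    measure: str
    amps: np.ndarray
    values: np.ndarray
    defined: np.ndarray
    freqs: np.ndarray | None = None
    timing: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    def value_at(self, amp: float, f: float | None = None) -> float:
        i = int(np.argmin(np.abs(self.amps - amp)))
        if self.freqs is None:
            return float(self.values[i])
        j = int(np.argmin(np.abs(self.freqs - f)))
        return float(self.values[i, j])


@dataclass(frozen=True)
class ExcitabilityCall:
    """Hodgkin class label with the evidence behind it."""

    class_label: str
    onset_amp: float
    onset_rate_hz: float
    max_count: int


@dataclass(frozen=True)
class BlockBounds:
    """Depolarization-block intervals on an intensity sweep: the
    contiguous high-spike-count region and the collapsed (low-count,
    still spiking) region above it, as (lo, hi) amplitude pairs on the
    sweep grid.  ``low`` is None when the curve never collapses."""

    high: tuple[float, float]
    low: tuple[float, float] | None


def _sweep_meta(timing: StimulusTiming, dt: float, threshold: float, refractory: float) -> dict:
    return {
        "t_on": timing.t_on,
        "duration": timing.duration,
        "dt": dt,
        "threshold": threshold,
        "refractory": refractory,
    }


def fI_curve(
    params: RGCParams | MLParams,
    amps,
    timing: StimulusTiming = STEP_TIMING,
    dt: float = DEFAULT_DT,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> SweepResult:
    """Spike count per constant-current step, one step per amplitude,
    each from the common resting state."""
    amps = np.asarray(list(amps), dtype=float)
    if len(amps) == 0:
        raise ValueError("amplitude axis must be non-empty")
    if np.any(amps < 0):
        raise ValueError("amplitudes must be non-negative")
    counts = np.zeros(len(amps))
    for i, amp in enumerate(amps):
        try:
            trace = simulate(params, constant_step(amp, timing), dt=dt)
        except IntegrationError as err:
            raise IntegrationError(err.t_fail) from ValueError(
                f"integration failed at amplitude {amp} uA/cm^2"
            )
        counts[i] = len(detect_spikes(trace, threshold, refractory))
    return SweepResult(
        model_id=model_id(params),
        measure="spike_count",
        amps=amps,
        values=counts,
        defined=np.ones(len(amps), dtype=bool),
        timing=_sweep_meta(timing, dt, threshold, refractory),
    )


def latency_curve(
    params: RGCParams | MLParams,
    amps,
    timing: StimulusTiming = STEP_TIMING,
    dt: float = DEFAULT_DT,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> SweepResult:
    """First-spike latency per constant-current step; undefined below
    threshold."""
    amps = np.asarray(list(amps), dtype=float)
    values = np.full(len(amps), np.nan)
    defined = np.zeros(len(amps), dtype=bool)
    for i, amp in enumerate(amps):
        trace = simulate(params, constant_step(amp, timing), dt=dt)
        train = detect_spikes(trace, threshold, refractory)
        lat = first_spike_latency(train, timing.t_on)
        values[i], defined[i] = lat.value, lat.defined
    return SweepResult(
        model_id=model_id(params),
        measure="first_spike_latency",
        amps=amps,
        values=values,
        defined=defined,
        timing=_sweep_meta(timing, dt, threshold, refractory),
    )


def periodic_response_cell(
    params: RGCParams | MLParams,
    f: float,
    amp: float,
    measure: str = "spikes_per_cycle",
    timing: StimulusTiming = GRID_TIMING,
    dt: float = DEFAULT_DT,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    discard_cycles: int = 0,
):
    """One rectified-sine simulation and its coding measure (a single
    cell of a frequency x amplitude grid)."""
    proto = rectified_sine(amp, f, timing)
    lo = timing.t_on + discard_cycles * (1000.0 / f)
    if lo >= proto.t_off:
        raise ValueError("discard_cycles leaves no analysis window")
    window = (lo, proto.t_off)
    trace = simulate(params, proto, dt=dt)
    train = detect_spikes(trace, threshold, refractory)
    if measure == "spikes_per_cycle":
        return spikes_per_cycle(train, proto, window)
    if measure == "spikes_per_second":
        return spikes_per_second(train, window)
    return first_spike_latency(train, timing.t_on)


def periodic_response_grid(
    params: RGCParams | MLParams,
    f_values,
    amp_values,
    measure: str = "spikes_per_cycle",
    timing: StimulusTiming = GRID_TIMING,
    dt: float = DEFAULT_DT,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    discard_cycles: int = 0,
) -> SweepResult:
    """One rectified-sine simulation per (frequency, amplitude) cell.

    ``measure`` is one of spikes_per_cycle, spikes_per_second or
    first_spike_latency.  By default the analysis window is the whole
    stimulus (the first cycle included, since onset effects are part of
    the phenomenon); ``discard_cycles`` drops that many initial cycles
    instead.  Per-cell integration failures are recorded as undefined
    cells in ``errors``, not raised.
    """
    if measure not in ("spikes_per_cycle", "spikes_per_second", "first_spike_latency"):
        raise ValueError(f"unknown measure {measure!r}")
    f_values = np.asarray(list(f_values), dtype=float)
    amp_values = np.asarray(list(amp_values), dtype=float)
    if len(f_values) == 0 or len(amp_values) == 0:
        raise ValueError("frequency and amplitude axes must be non-empty")
    values = np.full((len(amp_values), len(f_values)), np.nan)
    defined = np.zeros_like(values, dtype=bool)
    errors: list = []
    for i, amp in enumerate(amp_values):
        for j, f in enumerate(f_values):
            try:
                m = periodic_response_cell(
                    params, f, amp, measure, timing, dt,
                    threshold, refractory, discard_cycles,
                )
            except IntegrationError as err:
                errors.append((float(amp), float(f), str(err)))
                continue
            values[i, j], defined[i, j] = m.value, m.defined
    meta = _sweep_meta(timing, dt, threshold, refractory)
    meta["discard_cycles"] = discard_cycles
    return SweepResult(
        model_id=model_id(params),
        measure=measure,
        amps=amp_values,
        values=values,
        defined=defined,
        freqs=f_values,
        timing=meta,
        errors=errors,
    )


def classify_excitability(
    curve: SweepResult,
    single_spike_ceiling: int = SINGLE_SPIKE_CEILING,
    continuity_cutoff_hz: float = CONTINUITY_CUTOFF_HZ,
) -> ExcitabilityCall:
    """Assign a Hodgkin excitability class from an f-I spike-count curve.

    Rule order: Class III if the sweep maximum never exceeds the
    onset-spiking ceiling; otherwise evaluate the firing rate (count
    over the step, in Hz) at the smallest amplitude with repetitive
    firing (count above the ceiling): Class I if that onset rate falls
    below the continuity cutoff, Class II if it jumps in above it.
    Amplitudes with at most ``single_spike_ceiling`` spikes count as
    onset transients, not as repetitive firing — excitable-but-not-
    oscillating neurons (Class II near threshold, Class III anywhere)
    emit one or two onset spikes, and Hodgkin's criterion concerns the
    sustained-firing onset.
    """
    if curve.measure != "spike_count":
        raise ValueError("classification requires a spike-count curve")
    counts = curve.values
    if counts.max() == 0:
        raise UnclassifiableError("f-I curve is entirely subthreshold")
    max_count = int(counts.max())
    if max_count <= single_spike_ceiling:
        first = int(np.argmax(counts > 0))
        return ExcitabilityCall(
            class_label="III",
            onset_amp=float(curve.amps[first]),
            onset_rate_hz=float(counts[first] / (curve.timing["duration"] / 1000.0)),
            max_count=max_count,
        )
    first = int(np.argmax(counts > single_spike_ceiling))
    onset_rate = float(counts[first] / (curve.timing["duration"] / 1000.0))
    label = "I" if onset_rate < continuity_cutoff_hz else "II"
    return ExcitabilityCall(
        class_label=label,
        onset_amp=float(curve.amps[first]),
        onset_rate_hz=onset_rate,
        max_count=max_count,
    )


def _spike_count(params, amp: float, timing: StimulusTiming, dt: float) -> int:
    trace = simulate(params, constant_step(amp, timing), dt=dt)
    return len(detect_spikes(trace))


#: Longer steps for classification sweeps: 1000 ms steps resolve onset
#: rates down to 1 Hz, which a 500 ms step cannot (its resolution is
#: 2 Hz, too coarse near a Class I onset).
CLASSIFY_TIMING = StimulusTiming(t_on=50.0, duration=1000.0, tail=0.0)


def excitability_profile(
    params: RGCParams | MLParams,
    amp_max: float | None = None,
    n_coarse: int = 19,
    timing: StimulusTiming = CLASSIFY_TIMING,
    dt: float = DEFAULT_DT,
    single_spike_ceiling: int = SINGLE_SPIKE_CEILING,
    continuity_cutoff_hz: float = CONTINUITY_CUTOFF_HZ,
    onset_resolution: float = 0.002,
) -> tuple[SweepResult, ExcitabilityCall]:
    """f-I curve with fine resolution near the firing onset, plus its
    classification.

    A coarse sweep brackets the firing onset, bisection narrows the
    bracket to ``onset_resolution`` (uA/cm^2), and the first amplitude
    above it is appended to the curve so the onset rate is evaluated
    arbitrarily close to threshold.  Default sweep ranges:
    0-9 uA/cm^2 for RGC presets, 0-120 for ML.
    """
    if amp_max is None:
        amp_max = 9.0 if isinstance(params, RGCParams) else 120.0
    coarse = np.linspace(0.0, amp_max, n_coarse)
    curve = fI_curve(params, coarse, timing, dt)
    counts = curve.values
    if counts.max() <= single_spike_ceiling:
        return curve, classify_excitability(curve, single_spike_ceiling, continuity_cutoff_hz)
    first = int(np.argmax(counts > single_spike_ceiling))
    lo = 0.0 if first == 0 else float(coarse[first - 1])
    hi = float(coarse[first])
    while hi - lo > onset_resolution:
        mid = 0.5 * (lo + hi)
        if _spike_count(params, mid, timing, dt) > single_spike_ceiling:
            hi = mid
        else:
            lo = mid
    extra = np.array([hi])
    amps = np.unique(np.concatenate([coarse, extra]))
    curve = fI_curve(params, amps, timing, dt)
    call = classify_excitability(curve, single_spike_ceiling, continuity_cutoff_hz)
    return curve, call


def depolarization_block_bounds(
    curve: SweepResult, fraction: float = 0.5
) -> BlockBounds:
    """Locate the high-count and collapsed-count intensity regions.

    The high-count region is the maximal contiguous amplitude run whose
    spike count stays at or above ``fraction`` of the sweep maximum
    (the run containing the sweep argmax); the low-count region
    collects the amplitudes above that run that still spike but below
    the fraction.  Raises :class:`BlockNotApplicableError` when nothing
    spikes.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    counts = curve.values
    cmax = counts.max()
    if cmax == 0:
        raise BlockNotApplicableError("no spiking anywhere in the sweep")
    level = fraction * cmax
    peak = int(np.argmax(counts))
    i0 = peak
    while i0 > 0 and counts[i0 - 1] >= level:
        i0 -= 1
    i1 = peak
    while i1 < len(counts) - 1 and counts[i1 + 1] >= level:
        i1 += 1
    above = np.nonzero((np.arange(len(counts)) > i1) & (counts > 0) & (counts < level))[0]
    low = (
        (float(curve.amps[above[0]]), float(curve.amps[above[-1]]))
        if len(above)
        else None
    )
    return BlockBounds(
        high=(float(curve.amps[i0]), float(curve.amps[i1])),
        low=low,
    )


def freq_preference(row: np.ndarray) -> str:
    """Position of the firing-rate maximum along a frequency axis:
    'low' (first cell), 'interior' (band-pass) or 'high' (last cell).
    Ties resolve to the lowest frequency."""
    row = np.asarray(row, dtype=float)
    if np.all(np.isnan(row)) or np.nanmax(row) == 0:
        raise ValueError("row has no response; preference undefined")
    k = int(np.nanargmax(row))
    if k == 0:
        return "low"
    if k == len(row) - 1:
        return "high"
    return "interior"
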