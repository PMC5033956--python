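"""ganglion: conductance-based retinal ganglion cell and Morris-Lecar
simulation with spike-rate and spike-latency coding analysis.

The package simulates three intrinsically distinct retinal ganglion
cell phenotypes (repetitive spiking, tonic firing, phasic firing) and
the three Hodgkin excitability classes of the Morris-Lecar model under
constant and half-wave-rectified sinusoidal current drive, and analyzes
the responses with spikes-per-cycle and first-spike-latency measures.
"""

from .rgc import (
    RGCParams,
    RGCState,
    CurrentBreakdown,
    rgc_preset,
    rate_constants,
    steady_state_gate,
    calcium_reversal,
    membrane_currents,
    rgc_derivatives,
)
from .ml import MLParams, MLState, ml_preset, ml_steady_states, ml_derivatives
from .forcing import (
    StimulusProtocol,
    StimulusTiming,
    stimulus_value,
    constant_step,
    rectified_sine,
    build_protocol_grid,
)
from .integrate import (
    Trace,
    IntegrationError,
    RestNotConvergedError,
    find_rest,
    simulate,
)
from .spikes import (
    SpikeTrain,
    CodingMeasure,
    detect_spikes,
    spikes_per_cycle,
    spikes_per_second,
    first_spike_latency,
)
from .experiments import (
    SweepResult,
    ExcitabilityCall,
    BlockBounds,
    fI_curve,
    latency_curve,
    periodic_response_grid,
    classify_excitability,
    excitability_profile,
    depolarization_block_bounds,
)

__version__ = "0.1.0"

PRESETS = ("repetitive", "tonic", "phasic", "ml_class1", "ml_class2", "ml_class3")


def load_preset(name: str):
    """Load any of the six named presets by name."""
    if name in ("repetitive", "tonic", "phasic"):
        return rgc_preset(name)
    if name in ("ml_class1", "ml_class2", "ml_class3", "I", "II", "III"):
        return ml_preset(name)
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
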