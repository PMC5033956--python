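"""Optional heatmap rendering for frequency x amplitude grids.

Requires matplotlib (install the ``plot`` extra).  Rendered figures are
qualitative companions to the numeric grids; undefined cells (no
response) are left white.
"""

from __future__ import annotations

import numpy as np

from .experiments import SweepResult


def heatmap(result: SweepResult, ax=None, cmap: str = "jet"):
    """Render a 2-D sweep as a frequency x amplitude heatmap.

    Undefined cells are masked (shown white).  Returns the matplotlib
    Axes.
    """
    if result.freqs is None:
        raise ValueError("heatmap requires a 2-D (frequency x amplitude) sweep")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = np.ma.masked_invalid(result.values)
    mesh = ax.pcolormesh(result.freqs, result.amps, data, cmap=cmap, shading="nearest")
    ax.set_xlabel("stimulus frequency (Hz)")
    ax.set_ylabel("stimulus amplitude (uA/cm$^2$)")
    label = {
        "spikes_per_cycle": "firing rate (spikes/cycle)",
        "spikes_per_second": "firing rate (spikes/s)",
        "first_spike_latency": "first-spike latency (ms)",
    }.get(result.measure, result.measure)
    ax.set_title(f"{result.model_id}: {label}")
    ax.figure.colorbar(mesh, ax=ax)
    return ax
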