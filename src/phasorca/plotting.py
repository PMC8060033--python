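"""Phasor-plot helpers (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

from .calibration import PhasorCalibration
from .decay import phasor_array


def phasor_plot(
    phasors=None,
    cal: PhasorCalibration | None = None,
    gate_radius: float | None = None,
    ax=None,
):
    """Scatter phasors over the universal semicircle.

    Optionally overlays the calibration segment and the noise-gate disk.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "k-", lw=0.8)
    if phasors is not None:
        arr = phasor_array(phasors)
        ax.scatter(arr[:, 0], arr[:, 1], s=4, alpha=0.5)
    if cal is not None:
        ax.plot(
            [cal.p_free.g, cal.p_fret.g],
            [cal.p_free.s, cal.p_fret.s],
            "r--",
            lw=1.0,
            label="calibration segment",
        )
        gate_radius = gate_radius if gate_radius is not None else cal.gate_radius
    if gate_radius:
        phi = np.linspace(0, np.pi / 2, 100)
        ax.plot(gate_radius * np.cos(phi), gate_radius * np.sin(phi), "b:", lw=0.8)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.02, 0.65)
    ax.set_aspect("equal")
    return ax
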