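"""Rendering of cycle-averaged power maps as heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cyclemap import CycleMap

__all__ = ["plot_cycle_map"]


def plot_cycle_map(cycle_map: CycleMap, path=None, ax=None, vmax=None):
    """Heatmap of a cycle map (percent of cycle vs frequency), optionally saved."""
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    im = ax.imshow(
        cycle_map.power,
        origin="lower",
        aspect="auto",
        extent=(
            cycle_map.percent[0],
            cycle_map.percent[-1],
            cycle_map.frequencies[0],
            cycle_map.frequencies[-1],
        ),
        cmap="magma",
        vmax=vmax,
    )
    ax.set_xlabel("pedal cycle (%)")
    ax.set_ylabel("frequency (Hz)")
    title = " / ".join(s for s in (cycle_map.condition, cycle_map.block) if s)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="power")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax
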