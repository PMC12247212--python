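"""Basic overlay figure: observed sensorgram vs fitted model trace."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import ModelParameters, evaluate_trace
from .schedule import AssaySchedule

__all__ = ["overlay_plot"]


def overlay_plot(
    sg,
    schedule: AssaySchedule,
    params: ModelParameters,
    path: str | Path,
    title: str = "",
) -> None:
    """Save a data-vs-fit overlay with step boundaries marked."""
    mask = sg.kinetic_mask(schedule)
    t, obs = sg.times[mask], sg.responses[mask]
    fit = evaluate_trace(t, schedule, params)

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(t, obs, lw=0.8, color="0.4", label="data")
    ax.plot(t, fit, lw=1.5, color="crimson", label="global fit")
    boundary = 0.0
    for step in schedule.kinetic_steps[:-1]:
        boundary += step.duration
        ax.axvline(boundary, color="0.85", lw=0.6, zorder=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("response (nm)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
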