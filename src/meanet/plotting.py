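"""Raster plots of MEA recordings (headless-safe)."""

from __future__ import annotations

from pathlib import Path
from typing import IO

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .bursts import Burst
from .model import Recording

__all__ = ["render_raster"]


def render_raster(recording: Recording, sink: str | Path | IO[bytes],
                  bursts_by_electrode: dict[str, list[Burst]] | None = None,
                  dpi: int = 150) -> None:
    """Write a raster figure: one row per electrode in layout order, a tick
    per spike, and (optionally) shaded boxes spanning each detected burst."""
    eids = list(recording.layout.electrode_ids)
    fig, ax = plt.subplots(figsize=(10, max(2.0, 0.12 * len(eids))))
    positions = [recording.trains[eid].timestamps for eid in eids]
    if any(len(p) for p in positions):
        ax.eventplot(positions, lineoffsets=range(len(eids)), linelengths=0.8,
                     colors="k", linewidths=0.5)
    if bursts_by_electrode:
        for i, eid in enumerate(eids):
            for b in bursts_by_electrode.get(eid, []):
                ax.axvspan(b.start, b.end, ymin=(i + 0.1) / len(eids),
                           ymax=(i + 0.9) / len(eids), color="tab:red",
                           alpha=0.25, lw=0)
    ax.set_xlim(0, recording.epoch_duration)
    ax.set_ylim(-1, len(eids))
    ax.set_yticks(range(len(eids)))
    ax.set_yticklabels(eids, fontsize=4)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    title = " ".join(x for x in (recording.condition, recording.culture_id,
                                 f"DIV {recording.div}" if recording.div else "")
                     if x)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(sink, dpi=dpi)
    plt.close(fig)
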