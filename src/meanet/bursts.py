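"""Max-interval burst detection and per-electrode burst statistics.

A burst is a run of closely spaced spikes on a single electrode.  The
max-interval method parses a spike train in three phases:

1. *Scan* — walking the train in time order, a candidate burst opens at
   spike ``i`` when the interspike interval (ISI) to the next spike is at
   most ``max_isi_start``; the candidate then extends while each next ISI
   is at most ``max_isi_end``, and closes at the first larger gap.
2. *Merge* — consecutive candidates whose gap (next onset minus previous
   offset) is below ``min_ibi_merge`` are fused into one burst.
3. *Filter* — candidates shorter than ``min_burst_duration`` or with fewer
   than ``min_spikes_in_burst`` spikes are discarded.

Merging runs before filtering, so two small candidates can fuse into a
burst that survives the size filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Iterable, Literal

import numpy as np

from .model import Recording, SpikeTrain

__all__ = [
    "BurstDetectionConfig",
    "Burst",
    "ElectrodeBurstSummary",
    "detect_bursts",
    "detect_bursts_recording",
    "summarize_bursts",
    "write_burst_table",
]


@dataclass(frozen=True)
class BurstDetectionConfig:
    """Max-interval thresholds (seconds / counts).

    Defaults are the conventional max-interval settings used with
    commercial spike-train analysis software: 170 ms to start a burst,
    300 ms to end it, bursts closer than 200 ms merged, minimum duration
    10 ms, minimum 3 spikes.
    """

    max_isi_start: float = 0.17
    max_isi_end: float = 0.30
    min_ibi_merge: float = 0.20
    min_burst_duration: float = 0.01
    min_spikes_in_burst: int = 3

    def __post_init__(self):
        if min(self.max_isi_start, self.max_isi_end, self.min_ibi_merge,
               self.min_burst_duration) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.max_isi_start > self.max_isi_end:
            raise ValueError("max_isi_start must not exceed max_isi_end")
        if self.min_spikes_in_burst < 2:
            raise ValueError("min_spikes_in_burst must be at least 2")


@dataclass(frozen=True)
class Burst:
    """One detected burst: closed interval from first to last member spike."""

    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_bursts(train: SpikeTrain | np.ndarray,
                  config: BurstDetectionConfig = BurstDetectionConfig()
                  ) -> list[Burst]:
    """Parse one spike train into bursts via the three-phase max-interval scan.

    Accepts a :class:`SpikeTrain` or a sorted timestamp array.  Returns
    time-ordered, disjoint bursts; an empty or single-spike train yields
    no bursts.
    """
    ts = train.timestamps if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if ts.size < 2:
        return []
    isi = np.diff(ts)
    end_ok = isi <= config.max_isi_end
    start_ok = isi <= config.max_isi_start

    # Maximal runs of ISIs <= max_isi_end; within a run the candidate opens
    # at the first ISI <= max_isi_start and extends to the run's end, so each
    # run yields at most one candidate.
    edges = np.flatnonzero(np.diff(np.concatenate((
        [0], end_ok.astype(np.int8), [0]))))
    candidates: list[tuple[int, int]] = []  # spike index span [i0, i1] inclusive
    for rs, re in zip(edges[0::2], edges[1::2]):
        run_start_ok = start_ok[rs:re]
        if run_start_ok.any():
            k = rs + int(np.argmax(run_start_ok))
            candidates.append((k, re))

    # Phase 2: merge candidates separated by less than min_ibi_merge.
    merged: list[tuple[int, int]] = []
    for i0, i1 in candidates:
        if merged and ts[i0] - ts[merged[-1][1]] < config.min_ibi_merge:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))

    # Phase 3: duration and size filter.
    out = []
    for i0, i1 in merged:
        n = i1 - i0 + 1
        if n >= config.min_spikes_in_burst and \
                ts[i1] - ts[i0] >= config.min_burst_duration:
            out.append(Burst(float(ts[i0]), float(ts[i1]), n))
    return out


def detect_bursts_recording(recording: Recording,
                            config: BurstDetectionConfig = BurstDetectionConfig()
                            ) -> dict[str, list[Burst]]:
    """Burst lists per electrode, keyed by electrode id."""
    return {eid: detect_bursts(recording.trains[eid], config)
            for eid in recording.layout.electrode_ids}


@dataclass(frozen=True)
class ElectrodeBurstSummary:
    """Per-electrode burst statistics over one epoch.

    The inter-burst interval (IBI) is onset-to-onset by default;
    ``mean_ibi`` is None when the electrode has fewer than two bursts.
    """

    electrode_id: str
    n_bursts: int
    burst_rate_per_min: float
    durations: tuple[float, ...]
    ibis: tuple[float, ...]
    mean_ibi: float | None


def summarize_bursts(bursts: list[Burst], epoch_duration: float,
                     electrode_id: str = "",
                     ibi_mode: Literal["onset", "gap"] = "onset"
                     ) -> ElectrodeBurstSummary:
    """Summarize one electrode's burst list.

    ``ibi_mode='onset'`` measures onset-to-onset intervals; ``'gap'``
    measures previous-offset-to-next-onset.
    """
    if epoch_duration <= 0:
        raise ValueError("epoch_duration must be positive")
    n = len(bursts)
    onsets = [b.start for b in bursts]
    if ibi_mode == "onset":
        ibis = tuple(b - a for a, b in zip(onsets, onsets[1:]))
    elif ibi_mode == "gap":
        ibis = tuple(nb.start - pb.end for pb, nb in zip(bursts, bursts[1:]))
    else:
        raise ValueError(f"unknown ibi_mode {ibi_mode!r}")
    return ElectrodeBurstSummary(
        electrode_id=electrode_id,
        n_bursts=n,
        burst_rate_per_min=n / (epoch_duration / 60.0),
        durations=tuple(b.duration for b in bursts),
        ibis=ibis,
        mean_ibi=float(np.mean(ibis)) if n >= 2 else None,
    )


def write_burst_table(bursts_by_electrode: dict[str, list[Burst]],
                      sink: IO[str] | str) -> None:
    """Export bursts as delimited text: electrode_id, start_s, end_s, n_spikes."""
    close = False
    if isinstance(sink, str):
        sink = open(sink, "w", newline="")
        close = True
    try:
        w = csv.writer(sink, lineterminator="\n")
        w.writerow(("electrode_id", "start_s", "end_s", "n_spikes"))
        for eid in sorted(bursts_by_electrode):
            for b in bursts_by_electrode[eid]:
                w.writerow((eid, format(b.start, ".6f"), format(b.end, ".6f"),
                            b.n_spikes))
    finally:
        if close:
            sink.close()
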