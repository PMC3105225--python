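"""Core data types for multielectrode-array (MEA) recordings.

An MEA recording is a set of per-electrode spike trains (timestamps in
seconds from epoch start) on a known electrode grid, plus culture metadata
(day in vitro, condition, culture id).  This module defines the layout,
spike-train and recording containers, the canonical delimited-text spike
table, threshold-crossing spike detection on raw voltage traces, and
epoch windowing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "MEALayout",
    "SpikeTrain",
    "Recording",
    "RawTrace",
    "SpikeDetectionConfig",
    "SpikeTableParseError",
    "ValidationError",
    "standard_layout",
    "read_spike_table",
    "write_spike_table",
    "detect_spikes",
    "restrict_epoch",
]

#: timestamps are stored and serialized at microsecond resolution
TIME_DECIMALS = 6


class SpikeTableParseError(ValueError):
    """A malformed row in a delimited spike table (carries the line number)."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ValidationError(ValueError):
    """Input violates a structural invariant (unknown electrode, bad range...)."""


@dataclass(frozen=True)
class MEALayout:
    """Electrode grid geometry.

    The standard commercial layout is an 8x8 grid with the four corner
    positions absent (60 recording electrodes), 200 um pitch, 30 um
    electrode diameter.
    """

    electrode_ids: tuple[str, ...]
    grid_positions: tuple[tuple[int, int], ...]
    pitch_um: float = 200.0
    electrode_diameter_um: float = 30.0

    def __post_init__(self):
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValidationError("electrode ids must be unique")
        if len(self.grid_positions) != len(self.electrode_ids):
            raise ValidationError("one grid position per electrode required")
        if len(set(self.grid_positions)) != len(self.grid_positions):
            raise ValidationError("grid positions must be unique")
        if self.pitch_um <= 0:
            raise ValidationError("pitch must be positive")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def position_of(self, electrode_id: str) -> tuple[int, int]:
        return self.grid_positions[self.electrode_ids.index(electrode_id)]


def standard_layout(rows: int = 8, cols: int = 8, drop_corners: bool = True,
                    pitch_um: float = 200.0,
                    electrode_diameter_um: float = 30.0) -> MEALayout:
    """Rectangular grid layout; by default the 60-electrode 8x8-minus-corners grid.

    Electrode ids follow the column-row convention of the commercial
    8x8 arrays (e.g. "12" = column 1, row 2), generalized to ``C{c}R{r}``
    when the grid exceeds 9 rows or columns.
    """
    corners = {(0, 0), (0, cols - 1), (rows - 1, 0), (rows - 1, cols - 1)}
    ids: list[str] = []
    pos: list[tuple[int, int]] = []
    compact = rows <= 9 and cols <= 9
    for r in range(rows):
        for c in range(cols):
            if drop_corners and (r, c) in corners:
                continue
            ids.append(f"{c + 1}{r + 1}" if compact else f"C{c + 1}R{r + 1}")
            pos.append((r, c))
    return MEALayout(tuple(ids), tuple(pos), pitch_um, electrode_diameter_um)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike timestamps (seconds from epoch start) for one electrode."""

    electrode_id: str
    timestamps: np.ndarray
    epoch_duration: float

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if self.epoch_duration <= 0:
            raise ValidationError("epoch_duration must be positive")
        if ts.size:
            if ts[0] < 0 or ts[-1] > self.epoch_duration:
                raise ValidationError(
                    f"timestamps outside [0, {self.epoch_duration}] on "
                    f"electrode {self.electrode_id}")
            if np.any(np.diff(ts) <= 0):
                raise ValidationError(
                    f"timestamps not strictly increasing on electrode "
                    f"{self.electrode_id}")

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    def __len__(self) -> int:
        return self.n_spikes


@dataclass(frozen=True)
class Recording:
    """One epoch of one culture: a spike train per layout electrode + metadata."""

    layout: MEALayout
    trains: dict[str, SpikeTrain]
    epoch_duration: float = 900.0
    div: int = 0
    condition: str = ""
    culture_id: str = ""

    def __post_init__(self):
        known = set(self.layout.electrode_ids)
        for eid, train in self.trains.items():
            if eid not in known:
                raise ValidationError(f"unknown electrode id {eid!r}")
            if train.electrode_id != eid:
                raise ValidationError("train keyed under a different electrode id")
            if train.epoch_duration != self.epoch_duration:
                raise ValidationError("all trains must share the epoch duration")
        # every layout electrode has a train (possibly empty)
        missing = known - set(self.trains)
        for eid in sorted(missing):
            self.trains[eid] = SpikeTrain(eid, np.empty(0), self.epoch_duration)

    @property
    def total_spikes(self) -> int:
        return sum(t.n_spikes for t in self.trains.values())

    def train(self, electrode_id: str) -> SpikeTrain:
        return self.trains[electrode_id]

    def iter_trains(self) -> Iterable[SpikeTrain]:
        """Trains in layout order."""
        for eid in self.layout.electrode_ids:
            yield self.trains[eid]


@dataclass(frozen=True)
class RawTrace:
    """Sampled extracellular voltage (microvolts) from one electrode."""

    electrode_id: str
    samples: np.ndarray
    sampling_rate: float = 25_000.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")


@dataclass(frozen=True)
class SpikeDetectionConfig:
    """Fixed negative-threshold spike detection with waveform cutouts.

    Defaults mirror standard acquisition settings: -20 uV threshold
    (roughly 6-8 SD of baseline noise on a healthy electrode), 1 ms
    pre- and 2 ms post-crossing cutout at 25 kHz.  ``dead_time`` defaults
    to the post window so consecutive cutouts never overlap.
    """

    threshold_uv: float = -20.0
    pre_window_s: float = 0.001
    post_window_s: float = 0.002
    dead_time_s: float | None = None

    def __post_init__(self):
        if self.threshold_uv >= 0:
            raise ValidationError("threshold must be negative (negative-going spikes)")
        if self.pre_window_s <= 0 or self.post_window_s <= 0:
            raise ValidationError("cutout windows must be positive")
        if self.dead_time_s is None:
            object.__setattr__(self, "dead_time_s", self.post_window_s)


SPIKE_TABLE_HEADER = ("electrode_id", "time_s")


def read_spike_table(source: IO[str] | str, layout: MEALayout,
                     epoch_duration: float, *, div: int = 0,
                     condition: str = "", culture_id: str = "") -> Recording:
    """Read the canonical two-column spike table into a Recording.

    Rows are ``electrode_id,time_s`` with a required header.  Rows are
    sorted per electrode; an unknown electrode id or an out-of-epoch
    timestamp is a :class:`ValidationError`, a malformed row a
    :class:`SpikeTableParseError` carrying its line number.
    """
    close = False
    if isinstance(source, str):
        source = open(source, "r", newline="")
        close = True
    try:
        reader = csv.reader(source)
        try:
            header = next(reader)
        except StopIteration:
            header = None
        if header is not None and [h.strip() for h in header] != list(SPIKE_TABLE_HEADER):
            raise SpikeTableParseError(
                f"expected header {','.join(SPIKE_TABLE_HEADER)!r}, got {header!r}", 1)
        known = set(layout.electrode_ids)
        times: dict[str, list[float]] = {eid: [] for eid in layout.electrode_ids}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise SpikeTableParseError(f"expected 2 fields, got {len(row)}", lineno)
            eid = row[0].strip()
            try:
                t = float(row[1])
            except ValueError:
                raise SpikeTableParseError(f"unparseable timestamp {row[1]!r}", lineno)
            if t < 0:
                raise SpikeTableParseError(f"negative timestamp {t}", lineno)
            if eid not in known:
                raise ValidationError(f"unknown electrode id {eid!r} (line {lineno})")
            if t > epoch_duration:
                raise ValidationError(
                    f"timestamp {t} s exceeds epoch duration {epoch_duration} s "
                    f"(line {lineno})")
            times[eid].append(t)
        trains = {
            eid: SpikeTrain(eid, np.unique(np.round(ts, TIME_DECIMALS)), epoch_duration)
            for eid, ts in ((e, np.asarray(v, dtype=float)) for e, v in times.items())
        }
        return Recording(layout, trains, epoch_duration, div, condition, culture_id)
    finally:
        if close:
            source.close()


def write_spike_table(recording: Recording, sink: IO[str] | str) -> None:
    """Write a Recording as the canonical spike table.

    Rows are grouped by electrode id (lexicographic) then ascending time,
    at microsecond precision, so writing is deterministic and
    read/write round-trips are the identity.
    """
    close = False
    if isinstance(sink, str):
        sink = open(sink, "w", newline="")
        close = True
    try:
        writer = csv.writer(sink, lineterminator="\n")
        writer.writerow(SPIKE_TABLE_HEADER)
        for eid in sorted(recording.trains):
            for t in recording.trains[eid].timestamps:
                writer.writerow((eid, format(t, ".6f")))
    finally:
        if close:
            sink.close()


def detect_spikes(trace: RawTrace,
                  config: SpikeDetectionConfig = SpikeDetectionConfig()
                  ) -> tuple[SpikeTrain, list[np.ndarray]]:
    """Negative-threshold-crossing spike detection with waveform cutouts.

    A spike is registered at each sample where the voltage first crosses
    below ``threshold_uv`` (previous sample at or above it), provided the
    crossing is at least ``dead_time_s`` after the previous accepted spike
    and far enough from both trace boundaries for a full cutout
    (``round(pre*rate) + round(post*rate) + 1`` samples).  Spike time is
    the crossing sample divided by the sampling rate.
    """
    v = trace.samples
    if v.size == 0:
        raise ValidationError("empty trace")
    rate = trace.sampling_rate
    thr = config.threshold_uv
    below = v < thr
    crossings = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    pre_n = int(round(config.pre_window_s * rate))
    post_n = int(round(config.post_window_s * rate))
    dead_n = config.dead_time_s * rate
    times: list[float] = []
    cutouts: list[np.ndarray] = []
    last = -np.inf
    for i in crossings:
        if i - last < dead_n:
            continue
        if i - pre_n < 0 or i + post_n >= v.size:
            continue
        times.append(i / rate)
        cutouts.append(v[i - pre_n:i + post_n + 1].copy())
        last = i
    T = v.size / rate
    train = SpikeTrain(trace.electrode_id, np.asarray(times), T)
    return train, cutouts


def restrict_epoch(recording: Recording, t0: float, t1: float) -> Recording:
    """Restrict to the half-open window [t0, t1), re-zeroing times to t0."""
    if not (0 <= t0 < t1 <= recording.epoch_duration):
        raise ValueError(
            f"need 0 <= t0 < t1 <= {recording.epoch_duration}, got [{t0}, {t1})")
    T = t1 - t0
    trains = {}
    for eid, train in recording.trains.items():
        ts = train.timestamps
        kept = ts[(ts >= t0) & (ts < t1)] - t0
        trains[eid] = SpikeTrain(eid, np.round(kept, TIME_DECIMALS), T)
    return Recording(recording.layout, trains, T, recording.div,
                     recording.condition, recording.culture_id)
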