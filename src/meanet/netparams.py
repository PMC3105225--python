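"""The seven network-activity parameters of a developing MEA culture.

For one 15-minute recording the pipeline reports:

i.   total_spikes          — spikes summed over all electrodes
ii.  pct_spikes_in_bursts  — % of spikes inside any burst
iii. burst_rate            — mean bursts/min over electrodes bursting > 1/min
iv.  burst_duration        — mean burst duration (s) over those electrodes
v.   burst_pattern         — coefficient of variation, across electrodes, of
                             the per-electrode mean inter-burst interval
vi.  network_size          — electrodes bursting at least 1/min
vii. correlation_index     — mean pairwise spike-coincidence index

The correlation index of a pair of event trains is the coincidence count
within a +/-dt window, normalized so that two independent stationary
Poisson trains give ~1:

    CI = N_ab * T / (N_a * N_b * 2 * dt)

with N_ab the number of event pairs closer than dt.  Note the deliberate
threshold asymmetry between burst_rate/burst_duration (strictly more than
one burst per minute) and network_size (at least one burst per minute).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np

from .bursts import (Burst, BurstDetectionConfig, ElectrodeBurstSummary,
                     detect_bursts_recording, summarize_bursts)
from .model import Recording

__all__ = [
    "CorrelationConfig",
    "NetworkParameterSet",
    "PARAMETER_NAMES",
    "total_spikes",
    "pct_spikes_in_bursts",
    "burst_rate",
    "burst_duration",
    "burst_pattern",
    "network_size",
    "correlation_index_pair",
    "correlation_index",
    "compute_all",
    "summaries_for",
]

PARAMETER_NAMES = (
    "total_spikes",
    "pct_spikes_in_bursts",
    "burst_rate",
    "burst_duration",
    "burst_pattern",
    "network_size",
    "correlation_index",
)


@dataclass(frozen=True)
class CorrelationConfig:
    """Correlation-index settings.

    ``delta_t_s`` is the coincidence half-window (the 0.1 ms bin of the
    standard method).  ``event_source`` selects which events enter the
    index: every spike (default, maximal statistical power), only spikes
    inside bursts, or burst onsets.  Pairs enter the network mean when
    both electrodes have at least one event.
    """

    delta_t_s: float = 1e-4
    event_source: Literal["all_spikes", "burst_spikes", "burst_onsets"] = "all_spikes"
    pair_inclusion: Literal["both_nonempty"] = "both_nonempty"

    def __post_init__(self):
        if self.delta_t_s <= 0:
            raise ValueError("delta_t_s must be positive")


@dataclass(frozen=True)
class NetworkParameterSet:
    """The seven parameters for one recording; None marks an undefined value
    (e.g. burst statistics of a culture with no qualifying electrode)."""

    total_spikes: int
    pct_spikes_in_bursts: float | None
    burst_rate: float | None
    burst_duration: float | None
    burst_pattern: float | None
    network_size: int
    correlation_index: float | None

    def as_dict(self) -> dict[str, float | int | None]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


def total_spikes(recording: Recording) -> int:
    """Sum of all spikes detected in the recording epoch."""
    return recording.total_spikes


def pct_spikes_in_bursts(recording: Recording,
                         bursts_by_electrode: dict[str, list[Burst]]
                         ) -> float | None:
    """Percentage of spikes fired within bursts; None for a silent recording."""
    total = recording.total_spikes
    if total == 0:
        return None
    in_bursts = sum(b.n_spikes for bs in bursts_by_electrode.values() for b in bs)
    return 100.0 * in_bursts / total


def _qualifying(summaries: list[ElectrodeBurstSummary]) -> list[ElectrodeBurstSummary]:
    # "more than one burst per minute" — strict, unlike network_size
    return [s for s in summaries if s.burst_rate_per_min > 1.0]


def burst_rate(summaries: list[ElectrodeBurstSummary]) -> float | None:
    """Mean bursts/min across electrodes detecting more than one burst/min."""
    q = _qualifying(summaries)
    if not q:
        return None
    return float(np.mean([s.burst_rate_per_min for s in q]))


def burst_duration(summaries: list[ElectrodeBurstSummary]) -> float | None:
    """Mean burst duration (s), bursts pooled over qualifying electrodes."""
    durations = [d for s in _qualifying(summaries) for d in s.durations]
    if not durations:
        return None
    return float(np.mean(durations))


def burst_pattern(summaries: list[ElectrodeBurstSummary],
                  mode: Literal["across_electrodes", "within_electrode"] =
                  "across_electrodes") -> float | None:
    """Coefficient of variation of the inter-burst interval.

    Default reading: each electrode with >= 2 bursts contributes its mean
    IBI, and the CV (sample SD / mean) is taken across electrodes — high
    values mean electrodes burst on dissimilar schedules.  The alternative
    ``within_electrode`` mode averages each electrode's own IBI CV.
    """
    if mode == "across_electrodes":
        means = [s.mean_ibi for s in summaries if s.mean_ibi is not None]
        if len(means) < 2:
            return None
        m = float(np.mean(means))
        if m == 0:
            return None
        return float(np.std(means, ddof=1) / m)
    elif mode == "within_electrode":
        cvs = []
        for s in summaries:
            if len(s.ibis) >= 2 and np.mean(s.ibis) > 0:
                cvs.append(np.std(s.ibis, ddof=1) / np.mean(s.ibis))
        if not cvs:
            return None
        return float(np.mean(cvs))
    raise ValueError(f"unknown burst_pattern mode {mode!r}")


def network_size(summaries: list[ElectrodeBurstSummary]) -> int:
    """Number of electrodes detecting at least one burst per minute."""
    return sum(1 for s in summaries if s.burst_rate_per_min >= 1.0)


def correlation_index_pair(a: np.ndarray, b: np.ndarray, delta_t: float,
                           epoch_duration: float) -> float | None:
    """Coincidence index of two sorted event-time arrays; None if either empty.

    CI = N_ab * T / (N_a * N_b * 2 * delta_t), with N_ab the number of
    cross pairs within |x - y| <= delta_t.  Symmetric in its arguments and
    ~1 for independent Poisson trains.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        return None
    n_ab = int(np.sum(np.searchsorted(b, a + delta_t, side="right")
                      - np.searchsorted(b, a - delta_t, side="left")))
    return n_ab * epoch_duration / (a.size * b.size * 2.0 * delta_t)


def _event_lists(recording: Recording,
                 bursts_by_electrode: dict[str, list[Burst]],
                 source: str) -> dict[str, np.ndarray]:
    events = {}
    for eid in recording.layout.electrode_ids:
        ts = recording.trains[eid].timestamps
        if source == "all_spikes":
            events[eid] = ts
        elif source == "burst_onsets":
            events[eid] = np.asarray([b.start for b in bursts_by_electrode[eid]])
        elif source == "burst_spikes":
            keep = np.zeros(ts.size, dtype=bool)
            for b in bursts_by_electrode[eid]:
                lo, hi = np.searchsorted(ts, (b.start, b.end))
                keep[lo:hi + 1] = True
            events[eid] = ts[keep]
        else:
            raise ValueError(f"unknown event_source {source!r}")
    return events


def correlation_index(recording: Recording,
                      bursts_by_electrode: dict[str, list[Burst]],
                      config: CorrelationConfig = CorrelationConfig()
                      ) -> float | None:
    """Mean pairwise coincidence index over all unordered electrode pairs
    where both electrodes have at least one event; None if no pair qualifies."""
    events = _event_lists(recording, bursts_by_electrode, config.event_source)
    cis = []
    for ea, eb in combinations(recording.layout.electrode_ids, 2):
        ci = correlation_index_pair(events[ea], events[eb], config.delta_t_s,
                                    recording.epoch_duration)
        if ci is not None:
            cis.append(ci)
    if not cis:
        return None
    return float(np.mean(cis))


def summaries_for(recording: Recording,
                  bursts_by_electrode: dict[str, list[Burst]]
                  ) -> list[ElectrodeBurstSummary]:
    return [summarize_bursts(bursts_by_electrode[eid], recording.epoch_duration, eid)
            for eid in recording.layout.electrode_ids]


def compute_all(recording: Recording,
                burst_config: BurstDetectionConfig = BurstDetectionConfig(),
                correlation_config: CorrelationConfig = CorrelationConfig()
                ) -> NetworkParameterSet:
    """Run burst detection once and derive all seven parameters from it."""
    bursts = detect_bursts_recording(recording, burst_config)
    summaries = summaries_for(recording, bursts)
    return NetworkParameterSet(
        total_spikes=total_spikes(recording),
        pct_spikes_in_bursts=pct_spikes_in_bursts(recording, bursts),
        burst_rate=burst_rate(summaries),
        burst_duration=burst_duration(summaries),
        burst_pattern=burst_pattern(summaries),
        network_size=network_size(summaries),
        correlation_index=correlation_index(recording, bursts, correlation_config),
    )
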