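"""Independent brute-force oracles the test suite checks the library against.

These are deliberately literal re-statements of the contracts (per-spike
state machine, quadratic coincidence count, hand sum-of-squares) and share
no code with the implementation they verify.
"""

from __future__ import annotations

import numpy as np

from meanet.bursts import Burst, BurstDetectionConfig


def brute_force_bursts(timestamps, config: BurstDetectionConfig) -> list[Burst]:
    """Literal three-phase max-interval scan, one spike at a time."""
    ts = [float(t) for t in timestamps]
    n = len(ts)
    # phase 1: walk the train, opening on the start threshold and
    # extending on the end threshold
    candidates: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if ts[i + 1] - ts[i] <= config.max_isi_start:
            j = i + 1
            while j < n - 1 and ts[j + 1] - ts[j] <= config.max_isi_end:
                j += 1
            candidates.append((i, j))
            i = j + 1
        else:
            i += 1
    # phase 2: merge close candidates
    merged: list[tuple[int, int]] = []
    for a, b in candidates:
        if merged and ts[a] - ts[merged[-1][1]] < config.min_ibi_merge:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    # phase 3: size and duration filter
    return [Burst(ts[a], ts[b], b - a + 1) for a, b in merged
            if b - a + 1 >= config.min_spikes_in_burst
            and ts[b] - ts[a] >= config.min_burst_duration]


def quadratic_ci(a, b, delta_t: float, epoch_duration: float) -> float | None:
    """O(n^2) coincidence index: count every cross pair within delta_t."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        return None
    n_ab = sum(1 for x in a for y in b if abs(x - y) <= delta_t)
    return n_ab * epoch_duration / (a.size * b.size * 2.0 * delta_t)


def random_spike_train(rng: np.random.Generator, kind: str,
                       duration: float = 20.0) -> np.ndarray:
    """Poisson or burst-structured random train for oracle cross-checks."""
    if kind == "poisson":
        rate = rng.uniform(0.5, 15.0)
        n = rng.poisson(rate * duration)
        return np.unique(np.round(rng.uniform(0, duration, n), 6))
    # burst-structured: scattered burst cores plus sparse background
    n_bursts = rng.integers(1, 8)
    pieces = [np.round(rng.uniform(0, duration, rng.poisson(2.0 * duration / 20)), 6)]
    for t0 in rng.uniform(0, duration, n_bursts):
        n = rng.integers(2, 12)
        isis = rng.exponential(rng.uniform(0.01, 0.12), n - 1)
        pieces.append(np.round(t0 + np.concatenate(([0], np.cumsum(isis))), 6))
    ts = np.concatenate(pieces)
    return np.unique(ts[ts <= duration])


def random_burst_config(rng: np.random.Generator) -> BurstDetectionConfig:
    start = rng.uniform(0.03, 0.25)
    return BurstDetectionConfig(
        max_isi_start=start,
        max_isi_end=start + rng.uniform(0.0, 0.3),
        min_ibi_merge=rng.uniform(0.05, 0.5),
        min_burst_duration=rng.uniform(0.005, 0.05),
        min_spikes_in_burst=int(rng.integers(2, 6)),
    )


def anova_by_hand(groups: dict[str, list[float]]):
    """Textbook sum-of-squares one-way ANOVA: returns (F, df_b, df_w, mse)."""
    all_vals = [v for vals in groups.values() for v in vals]
    grand = sum(all_vals) / len(all_vals)
    ss_b = sum(len(v) * (sum(v) / len(v) - grand) ** 2 for v in groups.values())
    ss_w = sum((x - sum(v) / len(v)) ** 2 for v in groups.values() for x in v)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    mse = ss_w / df_w
    return ss_b / df_b / mse, df_b, df_w, mse
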