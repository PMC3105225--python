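"""Generative simulator of developing MEA network activity.

The model emulates spontaneous activity of dissociated hippocampal
cultures between DIV 5 and DIV 12: per-electrode tonic Poisson firing,
network-wide burst events that member electrodes join with per-event
probability and Gaussian onset jitter, and electrode-autonomous
(asynchronous) bursts.  Maturation is a linear trajectory between a
DIV-5 and a DIV-12 parameter endpoint; gene-knockdown phenotypes are
multiplier/override presets applied to that trajectory from an onset day
onward (optionally recovering, or freezing a parameter at an earlier
day's value).

Each electrode belongs to the synchronized network with probability
``member_prob`` (drawn once per recording); only members join network
events.  This is what grows the measured network size as cultures mature
and what a developmental-arrest phenotype freezes.  A per-electrode
excitability gain with coefficient of variation ``rate_heterogeneity_cv``
scales both the tonic rate and the autonomous burst rate, producing
electrode-to-electrode spread in firing and burst schedules.

All randomness flows from a single integer seed; identical seeds give
identical recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .model import MEALayout, Recording, SpikeTrain, TIME_DECIMALS, standard_layout

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ConditionPreset",
    "CONDITION_NAMES",
    "simulate_recording",
    "trajectory_config",
    "default_trajectory",
    "condition_preset",
    "condition_config",
    "simulate_experiment",
]

DIV_MIN, DIV_MAX = 5, 12


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one recording epoch.

    Rates are per electrode: ``tonic_rate`` in Hz, burst-event rates in
    events/min.  ``spikes_per_burst_mean`` is the Poisson mean spike count
    per burst (floored at 3) and ``intra_burst_isi_mean`` the exponential
    mean ISI inside a burst, so the expected burst envelope is roughly
    ``(spikes_per_burst_mean - 1) * intra_burst_isi_mean`` seconds.
    """

    layout: MEALayout = field(default_factory=standard_layout)
    epoch_duration: float = 900.0
    tonic_rate: float = 1.0
    net_burst_rate: float = 2.0
    participation_prob: float = 0.8
    member_prob: float = 1.0
    onset_jitter_sd: float = 0.02
    spikes_per_burst_mean: float = 10.0
    intra_burst_isi_mean: float = 0.02
    indep_burst_rate: float = 0.3
    rate_heterogeneity_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        for name in ("tonic_rate", "net_burst_rate", "onset_jitter_sd",
                     "spikes_per_burst_mean", "intra_burst_isi_mean",
                     "indep_burst_rate", "rate_heterogeneity_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("participation_prob", "member_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")


# numeric trajectory fields interpolated between DIV endpoints
_INTERP_FIELDS = (
    "tonic_rate", "net_burst_rate", "participation_prob", "member_prob",
    "onset_jitter_sd", "spikes_per_burst_mean", "intra_burst_isi_mean",
    "indep_burst_rate", "rate_heterogeneity_cv",
)


def _emit_burst(rng: np.random.Generator, onset: float, mean_spikes: float,
                mean_isi: float) -> np.ndarray:
    n = max(3, int(rng.poisson(mean_spikes)))
    if mean_isi > 0:
        isis = rng.exponential(mean_isi, n - 1)
    else:
        isis = np.zeros(n - 1)
    return onset + np.concatenate(([0.0], np.cumsum(isis)))


def simulate_recording(config: SimulationConfig, *, div: int = 0,
                       condition: str = "", culture_id: str = "") -> Recording:
    """Draw one seeded recording from the generative model.

    Per electrode: tonic homogeneous Poisson spikes at the gain-scaled
    rate; for network members, one burst per joined network event with
    jittered onset; autonomous bursts as an independent Poisson process.
    All spike times are restricted to [0, T], merged, sorted and
    de-duplicated at 1 microsecond resolution.
    """
    rng = np.random.default_rng(config.seed)
    T = config.epoch_duration
    n_events = rng.poisson(config.net_burst_rate / 60.0 * T)
    event_times = np.sort(rng.uniform(0.0, T, n_events))
    cv = config.rate_heterogeneity_cv
    trains: dict[str, SpikeTrain] = {}
    for eid in config.layout.electrode_ids:
        gain = float(rng.gamma(1.0 / cv**2, cv**2)) if cv > 0 else 1.0
        member = bool(rng.random() < config.member_prob)
        pieces: list[np.ndarray] = []
        n_tonic = rng.poisson(config.tonic_rate * gain * T)
        pieces.append(rng.uniform(0.0, T, n_tonic))
        if member and n_events:
            joined = event_times[rng.random(n_events) < config.participation_prob]
            for t0 in joined:
                onset = t0 + (rng.normal(0.0, config.onset_jitter_sd)
                              if config.onset_jitter_sd > 0 else 0.0)
                pieces.append(_emit_burst(rng, onset,
                                          config.spikes_per_burst_mean,
                                          config.intra_burst_isi_mean))
        n_indep = rng.poisson(config.indep_burst_rate * gain / 60.0 * T)
        for t0 in rng.uniform(0.0, T, n_indep):
            pieces.append(_emit_burst(rng, t0, config.spikes_per_burst_mean,
                                      config.intra_burst_isi_mean))
        ts = np.concatenate(pieces) if pieces else np.empty(0)
        ts = ts[(ts >= 0.0) & (ts <= T)]
        ts = np.unique(np.round(ts, TIME_DECIMALS))
        trains[eid] = SpikeTrain(eid, ts, T)
    return Recording(config.layout, trains, T, div, condition, culture_id)


@dataclass(frozen=True)
class Trajectory:
    """Linear developmental trajectory between DIV-5 and DIV-12 endpoints."""

    start: SimulationConfig
    end: SimulationConfig
    div_start: int = DIV_MIN
    div_end: int = DIV_MAX


def trajectory_config(traj: Trajectory, div: int) -> SimulationConfig:
    """Interpolate every numeric trajectory field linearly at the given DIV."""
    if not traj.div_start <= div <= traj.div_end:
        raise ValueError(f"div must be in [{traj.div_start}, {traj.div_end}]")
    frac = (div - traj.div_start) / (traj.div_end - traj.div_start)
    values = {
        name: (1 - frac) * getattr(traj.start, name) + frac * getattr(traj.end, name)
        for name in _INTERP_FIELDS
    }
    return replace(traj.start, **values)


def default_trajectory(layout: MEALayout | None = None,
                       epoch_duration: float = 900.0) -> Trajectory:
    """Control maturation: sparse, weakly coupled firing at DIV 5 growing
    into dense synchronized network bursting by DIV 12."""
    layout = layout if layout is not None else standard_layout()
    start = SimulationConfig(
        layout=layout, epoch_duration=epoch_duration,
        tonic_rate=0.2, net_burst_rate=0.5, participation_prob=0.6,
        member_prob=0.35, onset_jitter_sd=0.05, spikes_per_burst_mean=6.0,
        intra_burst_isi_mean=0.03, indep_burst_rate=0.3,
        rate_heterogeneity_cv=0.3)
    end = SimulationConfig(
        layout=layout, epoch_duration=epoch_duration,
        tonic_rate=0.6, net_burst_rate=3.0, participation_prob=0.9,
        member_prob=0.95, onset_jitter_sd=0.02, spikes_per_burst_mean=12.0,
        intra_burst_isi_mean=0.02, indep_burst_rate=0.5,
        rate_heterogeneity_cv=0.3)
    return Trajectory(start, end)


@dataclass(frozen=True)
class ConditionPreset:
    """A knockdown phenotype as trajectory edits active from an onset day.

    ``multipliers`` scale trajectory fields, ``overrides`` replace them,
    and ``freeze_at_div`` pins a field at its trajectory value on an
    earlier day (developmental arrest).  Effects apply for
    onset_div <= DIV, and stop at ``recovery_div`` if set (transient
    knockdown from which the culture recovers).
    """

    name: str
    effect_onset_div: int = DIV_MIN
    multipliers: dict[str, float] = field(default_factory=dict)
    overrides: dict[str, float] = field(default_factory=dict)
    freeze_at_div: dict[str, int] = field(default_factory=dict)
    recovery_div: int | None = None

    def __post_init__(self):
        if not DIV_MIN <= self.effect_onset_div <= DIV_MAX:
            raise ValueError("effect_onset_div must be within the recording window")

    def active(self, div: int) -> bool:
        if div < self.effect_onset_div:
            return False
        return self.recovery_div is None or div < self.recovery_div


#: Phenotype presets.  Control and the non-targeting siRNA (NTC) are
#: identical (no differential effect of transfection itself).  Effect
#: sizes other than the Dctn5 burst-event rate are qualitative fixture
#: constants chosen to be comfortably detectable at n = 8 cultures.
_PRESETS: dict[str, ConditionPreset] = {
    "control": ConditionPreset("control"),
    "ntc": ConditionPreset("ntc"),
    # shorter, tighter, more synchronous bursts; less tonic (out-of-burst)
    # firing -> %-in-bursts up, burst duration down, pattern CV down, CI up
    "tnik_kd": ConditionPreset(
        "tnik_kd", effect_onset_div=8,
        multipliers={"intra_burst_isi_mean": 0.4, "tonic_rate": 0.35,
                     "onset_jitter_sd": 0.3, "rate_heterogeneity_cv": 0.5},
        overrides={"participation_prob": 1.0}),
    # transient rise in burst rate and duration, recovered by DIV 12
    "dlg2_kd": ConditionPreset(
        "dlg2_kd", effect_onset_div=6, recovery_div=12,
        multipliers={"net_burst_rate": 1.9, "indep_burst_rate": 1.9,
                     "intra_burst_isi_mean": 1.5}),
    # minimal phenotype: longer bursts appearing only at DIV 12
    "disc1_kd": ConditionPreset(
        "disc1_kd", effect_onset_div=12,
        multipliers={"intra_burst_isi_mean": 1.5}),
    # burst-event rate pinned at 5.8/min from DIV 7 with full member
    # participation, while network growth is arrested at its DIV-6 extent
    "dctn5_kd": ConditionPreset(
        "dctn5_kd", effect_onset_div=7,
        overrides={"net_burst_rate": 5.8, "participation_prob": 1.0,
                   "indep_burst_rate": 0.0},
        freeze_at_div={"member_prob": 6}),
}

CONDITION_NAMES = tuple(_PRESETS)


def condition_preset(name: str) -> ConditionPreset:
    """Look up a named condition preset (control, ntc, or a knockdown)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; known: {', '.join(_PRESETS)}") from None


def condition_config(traj: Trajectory, preset: ConditionPreset, div: int,
                     seed: int = 0) -> SimulationConfig:
    """Trajectory config at one DIV with the preset's edits applied."""
    cfg = trajectory_config(traj, div)
    if preset.active(div):
        edits: dict[str, float] = {}
        for name, at_div in preset.freeze_at_div.items():
            edits[name] = getattr(trajectory_config(traj, at_div), name)
        for name, m in preset.multipliers.items():
            edits[name] = edits.get(name, getattr(cfg, name)) * m
        edits.update(preset.overrides)
        cfg = replace(cfg, **edits)
    return replace(cfg, seed=seed)


def _subseed(master_seed: int, *key: int) -> int:
    state = np.random.SeedSequence([int(master_seed), *key]).generate_state(1)[0]
    return int(state) % (2**31)


def simulate_experiment(conditions: list[str], n_cultures: int,
                        divs: list[int], trajectory: Trajectory | None = None,
                        seed: int = 0) -> list[Recording]:
    """Simulate a multi-condition longitudinal experiment.

    One recording per (condition, culture, DIV); cultures get independent
    deterministic sub-seeds derived from the master seed, and the same
    culture keeps its identity across days only through its label (days
    are drawn independently, matching daily cross-sectional analysis).
    """
    if n_cultures < 2:
        raise ValueError("need at least 2 cultures per condition for statistics")
    trajectory = trajectory if trajectory is not None else default_trajectory()
    recordings = []
    for ci, cond in enumerate(conditions):
        preset = condition_preset(cond)
        for cj in range(n_cultures):
            for div in divs:
                cfg = condition_config(trajectory, preset, div,
                                       seed=_subseed(seed, ci, cj, div))
                recordings.append(simulate_recording(
                    cfg, div=div, condition=cond, culture_id=f"{cond}-{cj + 1:02d}"))
    return recordings
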