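import io

import numpy as np
import pytest

from meanet.model import write_spike_table
from meanet.simulate import (ConditionPreset, SimulationConfig, Trajectory,
                             condition_config, condition_preset,
                             default_trajectory, simulate_experiment,
                             simulate_recording, trajectory_config)


def quiet_config(layout, **overrides):
    base = dict(layout=layout, epoch_duration=300.0, tonic_rate=0.0,
                net_burst_rate=0.0, participation_prob=1.0, member_prob=1.0,
                onset_jitter_sd=0.0, spikes_per_burst_mean=8.0,
                intra_burst_isi_mean=0.02, indep_burst_rate=0.0,
                rate_heterogeneity_cv=0.0, seed=1)
    base.update(overrides)
    return SimulationConfig(**base)


class TestSimulateRecording:
    def test_all_rates_zero_gives_empty_recording(self, small_layout):
        rec = simulate_recording(quiet_config(small_layout))
        assert rec.total_spikes == 0

    def test_seed_determinism_byte_identical_tables(self, small_layout):
        cfg = quiet_config(small_layout, tonic_rate=1.0, net_burst_rate=2.0,
                           onset_jitter_sd=0.02, rate_heterogeneity_cv=0.4)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_spike_table(simulate_recording(cfg), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seeds_differ(self, small_layout):
        cfg = quiet_config(small_layout, tonic_rate=1.0)
        a = simulate_recording(cfg)
        b = simulate_recording(SimulationConfig(**{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__}, "seed": 2}))
        assert a.total_spikes != b.total_spikes or any(
            not np.array_equal(a.trains[e].timestamps, b.trains[e].timestamps)
            for e in small_layout.electrode_ids)

    def test_tonic_spike_count_matches_poisson_expectation(self, small_layout):
        rate, T = 2.0, 300.0
        cfg = quiet_config(small_layout, tonic_rate=rate, epoch_duration=T)
        rec = simulate_recording(cfg)
        expected = rate * T * small_layout.n_electrodes
        assert abs(rec.total_spikes - expected) < 4 * np.sqrt(expected)

    def test_timestamps_within_epoch_and_unique(self, small_layout):
        cfg = quiet_config(small_layout, tonic_rate=5.0, net_burst_rate=4.0,
                           onset_jitter_sd=0.05)
        rec = simulate_recording(cfg)
        for train in rec.iter_trains():
            ts = train.timestamps
            assert np.all(np.diff(ts) > 0)
            if ts.size:
                assert 0 <= ts[0] and ts[-1] <= cfg.epoch_duration

    def test_invalid_config_rejected(self, small_layout):
        with pytest.raises(ValueError):
            quiet_config(small_layout, participation_prob=1.5)
        with pytest.raises(ValueError):
            quiet_config(small_layout, tonic_rate=-1.0)


class TestTrajectory:
    def test_endpoints_exact(self, small_layout):
        traj = default_trajectory(small_layout)
        assert trajectory_config(traj, 5) == traj.start
        cfg12 = trajectory_config(traj, 12)
        assert cfg12.tonic_rate == traj.end.tonic_rate
        assert cfg12.net_burst_rate == traj.end.net_burst_rate

    def test_linear_interpolation_fieldwise(self, small_layout):
        traj = default_trajectory(small_layout)
        # DIV range 5..12 has no integer midpoint; check the linear formula
        cfg8 = trajectory_config(traj, 8)
        frac = 3 / 7
        assert cfg8.tonic_rate == pytest.approx(
            (1 - frac) * traj.start.tonic_rate + frac * traj.end.tonic_rate)
        assert cfg8.member_prob == pytest.approx(
            (1 - frac) * traj.start.member_prob + frac * traj.end.member_prob)

    def test_out_of_range_div_rejected(self, small_layout):
        with pytest.raises(ValueError):
            trajectory_config(default_trajectory(small_layout), 4)


class TestPresets:
    def test_control_and_ntc_are_identity(self, small_layout):
        traj = default_trajectory(small_layout)
        for name in ("control", "ntc"):
            preset = condition_preset(name)
            assert not preset.multipliers and not preset.overrides
            assert condition_config(traj, preset, 9, seed=5) == \
                condition_config(traj, condition_preset("control"), 9, seed=5)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            condition_preset("nonexistent_kd")

    def test_dctn5_overrides_event_rate_and_freezes_membership(self, small_layout):
        traj = default_trajectory(small_layout)
        preset = condition_preset("dctn5_kd")
        before = condition_config(traj, preset, 6)
        assert before == condition_config(traj, condition_preset("control"), 6)
        after = condition_config(traj, preset, 9)
        assert after.net_burst_rate == pytest.approx(5.8)
        assert after.member_prob == pytest.approx(
            trajectory_config(traj, 6).member_prob)

    def test_tnik_shortens_bursts_and_tightens_synchrony(self, small_layout):
        traj = default_trajectory(small_layout)
        control = condition_config(traj, condition_preset("control"), 10)
        kd = condition_config(traj, condition_preset("tnik_kd"), 10)
        assert kd.intra_burst_isi_mean < control.intra_burst_isi_mean
        assert kd.tonic_rate < control.tonic_rate
        assert kd.onset_jitter_sd < control.onset_jitter_sd

    def test_dlg2_effect_recovers_by_div_12(self, small_layout):
        traj = default_trajectory(small_layout)
        preset = condition_preset("dlg2_kd")
        mid = condition_config(traj, preset, 9)
        assert mid.net_burst_rate > trajectory_config(traj, 9).net_burst_rate
        recovered = condition_config(traj, preset, 12)
        assert recovered == condition_config(traj, condition_preset("control"), 12)

    def test_onset_outside_window_rejected(self):
        with pytest.raises(ValueError):
            ConditionPreset("bad", effect_onset_div=3)


class TestSimulateExperiment:
    def test_bookkeeping_distinct_labels(self, small_layout):
        recs = simulate_experiment(["control", "ntc", "dctn5_kd"], 2, [5, 12],
                                   default_trajectory(small_layout,
                                                      epoch_duration=60.0),
                                   seed=3)
        labels = {(r.condition, r.culture_id, r.div) for r in recs}
        assert len(recs) == 12 and len(labels) == 12

    def test_master_seed_determinism(self, small_layout):
        traj = default_trajectory(small_layout, epoch_duration=60.0)
        a = simulate_experiment(["control", "ntc"], 2, [8], traj, seed=3)
        b = simulate_experiment(["control", "ntc"], 2, [8], traj, seed=3)
        for ra, rb in zip(a, b):
            for eid in small_layout.electrode_ids:
                np.testing.assert_array_equal(ra.trains[eid].timestamps,
                                              rb.trains[eid].timestamps)

    def test_cultures_get_independent_draws(self, small_layout):
        traj = default_trajectory(small_layout, epoch_duration=120.0)
        recs = simulate_experiment(["control"], 2, [12], traj, seed=3)
        assert not np.array_equal(recs[0].trains["21"].timestamps,
                                  recs[1].trains["21"].timestamps)

    def test_single_culture_rejected(self, small_layout):
        with pytest.raises(ValueError):
            simulate_experiment(["control"], 1, [5],
                                default_trajectory(small_layout), seed=0)

    def test_maturation_total_spikes_increase(self, small_layout):
        traj = default_trajectory(small_layout, epoch_duration=120.0)
        recs = simulate_experiment(["control"], 4, [5, 12], traj, seed=11)
        by_div = {5: [], 12: []}
        for r in recs:
            by_div[r.div].append(r.total_spikes)
        assert np.mean(by_div[12]) > np.mean(by_div[5])
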