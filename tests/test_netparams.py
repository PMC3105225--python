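import numpy as np
import pytest

from meanet.bursts import Burst, BurstDetectionConfig, detect_bursts_recording
from meanet.model import Recording, SpikeTrain
from meanet.netparams import (CorrelationConfig, burst_duration, burst_pattern,
                              burst_rate, compute_all, correlation_index,
                              correlation_index_pair, network_size,
                              pct_spikes_in_bursts, summaries_for, total_spikes)
from meanet.bursts import ElectrodeBurstSummary
from oracles import quadratic_ci


def summary(rate, mean_ibi=None, durations=(), ibis=()):
    return ElectrodeBurstSummary("e", int(rate), rate, tuple(durations),
                                 tuple(ibis), mean_ibi)


class TestScalarParameters:
    def test_total_spikes_sums_electrodes(self, worked_recording):
        assert total_spikes(worked_recording) == 16

    def test_total_spikes_empty(self, quad_layout):
        assert total_spikes(Recording(quad_layout, {}, 60.0)) == 0

    def test_pct_spikes_in_bursts(self, worked_recording):
        bursts = detect_bursts_recording(worked_recording)
        # 9 + 3 burst spikes of 16 total
        assert pct_spikes_in_bursts(worked_recording, bursts) == pytest.approx(75.0)

    def test_pct_missing_for_silent_recording(self, quad_layout):
        rec = Recording(quad_layout, {}, 60.0)
        assert pct_spikes_in_bursts(rec, {e: [] for e in quad_layout.electrode_ids}) \
            is None

    def test_pct_zero_when_no_bursts(self, worked_recording):
        empty = {e: [] for e in worked_recording.layout.electrode_ids}
        assert pct_spikes_in_bursts(worked_recording, empty) == 0.0

    def test_burst_rate_excludes_rates_at_or_below_one(self):
        rates = [summary(r) for r in (1.333, 2.0, 0.333, 0.0)]
        assert burst_rate(rates) == pytest.approx((1.333 + 2.0) / 2)

    def test_burst_rate_missing_when_none_qualify(self):
        assert burst_rate([summary(1.0), summary(0.5)]) is None

    def test_burst_duration_pools_qualifying_electrodes(self):
        s = [summary(2.0, durations=(0.1, 0.3)), summary(0.5, durations=(9.0,))]
        assert burst_duration(s) == pytest.approx(0.2)

    def test_burst_duration_missing_when_none_qualify(self):
        assert burst_duration([summary(0.5, durations=(0.1,))]) is None

    def test_network_size_uses_inclusive_threshold(self):
        s = [summary(r) for r in (1.333, 2.0, 0.333, 0.0, 1.0)]
        assert network_size(s) == 3

    def test_burst_rate_qualifiers_subset_of_network_size(self):
        s = [summary(r) for r in (0.2, 1.0, 1.5, 3.0)]
        n_rate = sum(1 for x in s if x.burst_rate_per_min > 1.0)
        assert n_rate <= network_size(s)


class TestBurstPattern:
    def test_identical_mean_ibis_give_zero_cv(self):
        s = [summary(2.0, mean_ibi=10.0) for _ in range(3)]
        assert burst_pattern(s) == pytest.approx(0.0)

    def test_two_electrode_cv(self):
        s = [summary(2.0, mean_ibi=5.0), summary(2.0, mean_ibi=15.0)]
        # sample sd 7.0711, mean 10
        assert burst_pattern(s) == pytest.approx(0.70711, abs=1e-5)

    def test_missing_below_two_contributors(self):
        assert burst_pattern([summary(2.0, mean_ibi=10.0), summary(0.0)]) is None

    def test_within_electrode_mode(self):
        s = [summary(3.0, mean_ibi=10.0, ibis=(5.0, 15.0))]
        assert burst_pattern(s, mode="within_electrode") == \
            pytest.approx(np.std([5, 15], ddof=1) / 10.0)


class TestCorrelationIndexPair:
    def test_identical_isolated_trains_closed_form(self):
        a = np.arange(10) * 10.0
        # CI = T / (N * 2 dt)
        assert correlation_index_pair(a, a, 1e-4, 900.0) == \
            pytest.approx(900.0 / (10 * 2e-4))

    def test_no_coincidences_gives_zero(self):
        a = np.array([1.0, 2.0])
        b = np.array([1.5, 2.5])
        assert correlation_index_pair(a, b, 1e-4, 900.0) == 0.0

    def test_empty_train_gives_missing(self):
        assert correlation_index_pair(np.empty(0), np.array([1.0]), 1e-4, 900) is None

    def test_symmetry_and_time_shift_invariance(self):
        rng = np.random.default_rng(3)
        a = np.sort(rng.uniform(0, 100, 200))
        b = np.sort(rng.uniform(0, 100, 150))
        ci = correlation_index_pair(a, b, 1e-3, 100.0)
        assert correlation_index_pair(b, a, 1e-3, 100.0) == pytest.approx(ci)
        assert correlation_index_pair(a + 7.0, b + 7.0, 1e-3, 100.0) == \
            pytest.approx(ci)

    def test_scales_linearly_with_epoch_duration(self):
        rng = np.random.default_rng(4)
        a = np.sort(rng.uniform(0, 100, 100))
        b = np.sort(rng.uniform(0, 100, 100))
        assert correlation_index_pair(a, b, 1e-3, 200.0) == \
            pytest.approx(2 * correlation_index_pair(a, b, 1e-3, 100.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 50, rng.integers(1, 120)))
        b = np.sort(rng.uniform(0, 50, rng.integers(1, 120)))
        assert correlation_index_pair(a, b, 0.05, 50.0) == \
            pytest.approx(quadratic_ci(a, b, 0.05, 50.0))

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            correlation_index_pair(np.array([1.0]), np.array([1.0]), 0.0, 10.0)


class TestNetworkCorrelationIndex:
    def test_two_identical_electrodes_equal_pairwise_value(self, quad_layout):
        ts = np.arange(10) * 5.0 + 1.0
        trains = {"11": SpikeTrain("11", ts, 60.0),
                  "21": SpikeTrain("21", ts.copy(), 60.0)}
        rec = Recording(quad_layout, trains, 60.0)
        bursts = {e: [] for e in quad_layout.electrode_ids}
        ci = correlation_index(rec, bursts)
        assert ci == pytest.approx(60.0 / (10 * 2e-4))

    def test_all_empty_gives_missing(self, quad_layout):
        rec = Recording(quad_layout, {}, 60.0)
        bursts = {e: [] for e in quad_layout.electrode_ids}
        assert correlation_index(rec, bursts) is None

    def test_burst_onset_event_source(self, quad_layout):
        trains = {"11": SpikeTrain("11", np.array([1.0, 1.01, 1.02]), 60.0),
                  "21": SpikeTrain("21", np.array([1.0, 1.01, 1.02]), 60.0)}
        rec = Recording(quad_layout, trains, 60.0)
        bursts = {e: [] for e in quad_layout.electrode_ids}
        bursts["11"] = [Burst(1.0, 1.02, 3)]
        bursts["21"] = [Burst(1.0, 1.02, 3)]
        cfg = CorrelationConfig(event_source="burst_onsets")
        # one onset each, coincident: CI = 1 * T / (1 * 1 * 2 dt)
        assert correlation_index(rec, bursts, cfg) == \
            pytest.approx(60.0 / 2e-4)


class TestComputeAll:
    def test_silent_recording(self, quad_layout):
        params = compute_all(Recording(quad_layout, {}, 60.0))
        assert params.total_spikes == 0
        assert params.network_size == 0
        for name in ("pct_spikes_in_bursts", "burst_rate", "burst_duration",
                     "burst_pattern", "correlation_index"):
            assert getattr(params, name) is None

    def test_composition_identity(self, worked_recording):
        bcfg, ccfg = BurstDetectionConfig(), CorrelationConfig()
        params = compute_all(worked_recording, bcfg, ccfg)
        bursts = detect_bursts_recording(worked_recording, bcfg)
        summaries = summaries_for(worked_recording, bursts)
        assert params.total_spikes == total_spikes(worked_recording)
        assert params.pct_spikes_in_bursts == \
            pct_spikes_in_bursts(worked_recording, bursts)
        assert params.burst_rate == burst_rate(summaries)
        assert params.burst_duration == burst_duration(summaries)
        assert params.burst_pattern == burst_pattern(summaries)
        assert params.network_size == network_size(summaries)
        assert params.correlation_index == \
            correlation_index(worked_recording, bursts, ccfg)

    def test_worked_fixture_values(self, worked_recording):
        params = compute_all(worked_recording)
        assert params.total_spikes == 16
        assert params.pct_spikes_in_bursts == pytest.approx(75.0)
        # only electrode 11 (3 bursts/min) qualifies for rate and duration
        assert params.burst_rate == pytest.approx(3.0)
        assert params.burst_duration == pytest.approx(0.1, abs=1e-9)
        assert params.burst_pattern is None  # a single contributing electrode
        assert params.network_size == 2
        assert params.pct_spikes_in_bursts <= 100.0
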