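"""Burst separation, spike density, network-burst detection and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trainset
from meanet import (BurstTrain, NetworkBurst, culture_metrics,
                    detect_network_bursts, label_background, spike_density)
from meanet.types import BACKGROUND, BURST_CANDIDATE


def naive_two_step(trains: dict[int, np.ndarray], theta1: float,
                   theta2: float) -> dict[int, np.ndarray]:
    """Independent hand-traceable implementation of the two-step rule."""
    labels = {}
    survivors = []  # (eid, idx, time)
    for eid, t in trains.items():
        lab = np.full(t.size, BURST_CANDIDATE)
        for i in range(t.size):
            pre = t[i] - t[i - 1] if i > 0 else np.inf
            post = t[i + 1] - t[i] if i < t.size - 1 else np.inf
            if pre > theta1 and post > theta1:
                lab[i] = BACKGROUND
            else:
                survivors.append((eid, i, t[i]))
        labels[eid] = lab
    survivors.sort(key=lambda x: x[2])
    for k, (eid, i, tk) in enumerate(survivors):
        pre = tk - survivors[k - 1][2] if k > 0 else np.inf
        post = survivors[k + 1][2] - tk if k < len(survivors) - 1 else np.inf
        if pre > theta2 and post > theta2:
            labels[eid][i] = BACKGROUND
    return labels


class TestLabelBackground:
    def test_single_spike_is_background_stage1(self):
        s = make_trainset({0: [5.0]}, 10.0)
        lab = label_background(s)
        assert lab.labels[0][0] == BACKGROUND
        assert lab.stage[0][0] == 1

    def test_regular_fast_train_no_stage1_background(self):
        # 50 ms ISIs < theta1 = 100 ms: stage 1 labels nothing
        s = make_trainset({0: np.arange(0.0, 5.0, 0.05)}, 5.0)
        lab = label_background(s)
        assert not np.any(lab.stage[0] == 1)
        # but the pooled ISIs (50 ms) exceed theta2 = 5 ms: stage 2 takes all
        assert np.all(lab.stage[0] == 2)

    def test_sparse_synchronous_volleys_hand_trace(self):
        # 3 electrodes firing simultaneously every 10 s: per-electrode ISIs
        # of 10 s exceed theta1, so stage 1 labels all 9 spikes background
        trains = {e: [10.0, 20.0, 30.0] for e in range(3)}
        s = make_trainset(trains, 40.0)
        lab = label_background(s)
        for e in range(3):
            assert np.all(lab.labels[e] == BACKGROUND)
            assert np.all(lab.stage[e] == 1)

    def test_burst_spikes_stay_candidates(self):
        # a dense volley across electrodes: nothing is isolated at either step
        base = np.array([10.0, 10.002, 10.004, 10.006])
        s = make_trainset({0: base, 1: base + 0.001}, 20.0)
        lab = label_background(s)
        assert lab.n_background() == 0
        assert lab.n_burst_candidates() == 8

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_oracle(self, data):
        n_el = data.draw(st.integers(1, 3))
        trains = {}
        for e in range(n_el):
            n = data.draw(st.integers(0, 6))
            ts = sorted(data.draw(st.lists(
                st.floats(0.0, 10.0, allow_nan=False), min_size=n,
                max_size=n, unique=True)))
            trains[e] = np.array(ts)
        s = make_trainset(trains, 10.0)
        lab = label_background(s, 0.1, 0.005)
        oracle = naive_two_step(trains, 0.1, 0.005)
        for e in trains:
            np.testing.assert_array_equal(lab.labels[e], oracle[e])


class TestSpikeDensity:
    def test_single_spike_peak_and_area(self):
        s = make_trainset({0: [5.0]}, 10.0)
        d = spike_density(s)
        i = np.argmax(d.values)
        assert d.times[i] == pytest.approx(5.0, abs=d.dt)
        assert d.values[i] == pytest.approx(1.0, abs=1e-9)
        area = np.trapezoid(d.values, d.times)
        assert area == pytest.approx(0.050 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_coincident_spikes_superpose(self):
        s = make_trainset({0: [5.0], 1: [5.0]}, 10.0)
        d = spike_density(s)
        assert d.values.max() == pytest.approx(2.0, abs=1e-9)

    def test_empty_trainset_zero_density(self):
        s = make_trainset({0: []}, 10.0)
        d = spike_density(s)
        assert np.all(d.values == 0.0)


def volley_trainset(burst_times, n_electrodes=60, spikes_per_el=10,
                    width=0.1, duration=60.0):
    """Synchronous volleys: every electrode fires `spikes_per_el` spikes
    spread over `width` seconds at each burst time."""
    trains = {}
    for e in range(n_electrodes):
        t = np.concatenate([bt + np.linspace(0, width, spikes_per_el)
                            for bt in burst_times])
        trains[e] = np.sort(t)
    return make_trainset(trains, duration)


class TestDetectNetworkBursts:
    def test_flat_subthreshold_density_no_bursts(self):
        s = make_trainset({0: [1.0], 1: [30.0]}, 60.0)
        d = spike_density(s)
        bt = detect_network_bursts(d, scale_with_active=False)
        assert bt.n_bursts == 0

    def test_two_planted_volleys(self):
        s = volley_trainset([20.0, 30.0])
        d = spike_density(s)
        bt = detect_network_bursts(d, n_active=60)
        assert bt.n_bursts == 2
        assert bt.ibis[0] == pytest.approx(10.0, abs=0.5)
        assert abs(bt.onsets[0] - 20.0) < 0.15

    def test_burst_size_close_to_spike_count(self):
        s = volley_trainset([20.0, 40.0])
        d = spike_density(s)
        bt = detect_network_bursts(d, n_active=60)
        planted_per_burst = 600
        for b in bt.bursts:
            assert b.size == pytest.approx(planted_per_burst, rel=0.10)

    def test_total_size_mass_conservation(self, bursting_culture):
        d = spike_density(bursting_culture)
        bt = detect_network_bursts(d, n_active=bursting_culture.n_electrodes)
        assert bt.sizes.sum() <= bursting_culture.n_spikes * 1.05

    def test_threshold_monotonicity(self, bursting_culture):
        d = spike_density(bursting_culture)
        counts = [detect_network_bursts(d, threshold=thr, n_active=60).n_bursts
                  for thr in (5.0, 10.0, 20.0, 40.0)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_windows_disjoint_positive_ibis(self, bursting_culture):
        d = spike_density(bursting_culture)
        bt = detect_network_bursts(d, n_active=bursting_culture.n_electrodes)
        assert bt.n_bursts > 5
        assert np.all(bt.onsets[1:] >= bt.offsets[:-1])
        assert np.all(bt.ibis > 0)
        assert np.all(bt.durations > 0)

    def test_threshold_scales_with_active_count(self):
        # 30 active electrodes: effective threshold 5; a volley of half the
        # reference strength is still detected under proportional scaling
        s = volley_trainset([20.0], n_electrodes=30)
        d = spike_density(s)
        scaled = detect_network_bursts(d, n_active=30)
        fixed = detect_network_bursts(d, n_active=30, scale_with_active=False)
        assert scaled.n_bursts == fixed.n_bursts == 1
        assert scaled.durations[0] > fixed.durations[0]


class TestCultureMetrics:
    def test_no_bursts(self):
        s = make_trainset({0: np.linspace(0, 100, 200)}, 1200.0)
        bt = BurstTrain(bursts=[])
        m = culture_metrics(s, None, bt)
        assert m.burst_rate == 0.0
        assert m.pct_spikes_in_bursts == 0.0
        assert np.isnan(m.mean_burst_duration)
        assert np.isnan(m.mean_ibi)

    def test_mfr_final_div_normalization(self):
        # 12000 spikes / 1200 s / 10 final-DIV active electrodes = 1.0 Hz
        trains = {e: np.linspace(0.1, 1199.9, 3000) for e in range(4)}
        s = make_trainset(trains, 1200.0)
        m = culture_metrics(s, None, None, n_active_at_final_div=10)
        assert m.mfr == pytest.approx(1.0)

    def test_all_spikes_in_windows_is_100pct(self):
        s = make_trainset({0: [1.0, 1.1, 5.0], 1: [1.05, 4.9]}, 10.0)
        bt = BurstTrain(bursts=[NetworkBurst(0.9, 1.2, 3.0),
                                NetworkBurst(4.8, 5.1, 2.0)])
        m = culture_metrics(s, None, bt)
        assert m.pct_spikes_in_bursts == 100.0
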