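"""Generator correctness: planted statistics, determinism, presets, raw synthesis."""

import numpy as np
import pytest
from scipy import stats as sstats

from meanet import (DetectionParams, SimulationConfig, default_presets,
                    detect_spikes, simulate_culture, simulate_study,
                    synthesize_raw)
from meanet.synthetic import CONTROL, DEFICIENT, child_seed


class TestSimulateCulture:
    def test_no_sources_gives_empty_trains(self):
        cfg = SimulationConfig(participation_prob=0.0, background_rate=0.0,
                               seed=0, duration=100.0)
        s = simulate_culture(cfg)
        assert s.n_spikes == 0
        assert all(t.size == 0 for t in s.trains.values())

    def test_background_poisson_count(self):
        # 5 Hz x 1200 s x 60 electrodes: total count within 3 SD of 360000
        cfg = SimulationConfig(background_rate=5.0, participation_prob=0.0,
                               duration=1200.0, n_electrodes=60, seed=3)
        s = simulate_culture(cfg)
        expected = 5.0 * 1200 * 60
        assert abs(s.n_spikes - expected) < 3 * np.sqrt(expected)

    def test_planted_burst_count_matches_renewal_oracle(self):
        # oracle: the count distribution of a gamma renewal process on
        # [0, T], simulated directly from scipy gamma draws
        mean, cv, T = 10.0, 0.5, 1200.0
        shape, scale = 1 / cv**2, mean * cv**2
        oracle_rng = np.random.default_rng(999)
        counts = []
        for _ in range(300):
            arr = sstats.gamma.rvs(shape, scale=scale, size=200,
                                   random_state=oracle_rng)
            counts.append(np.searchsorted(np.cumsum(arr), T))
        mu, sd = np.mean(counts), np.std(counts)

        cfg = SimulationConfig(burst_ibi_mean=mean, burst_ibi_cv=cv,
                               duration=T, background_rate=0.0, seed=7)
        s = simulate_culture(cfg)
        assert abs(s.ground_truth.n_bursts - mu) < 3.5 * sd

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=11, duration=120.0)
        a = simulate_culture(cfg)
        b = simulate_culture(cfg)
        for eid in a.trains:
            np.testing.assert_array_equal(a.trains[eid], b.trains[eid])
        np.testing.assert_array_equal(a.ground_truth.burst_onsets,
                                      b.ground_truth.burst_onsets)

    def test_planted_rates_recoverable(self):
        # background rate, burst rate and burst duration estimated from the
        # ground truth converge to the configured values (1200 s, 3 SE)
        cfg = SimulationConfig(seed=5, duration=1200.0, background_rate=0.5,
                               burst_ibi_mean=12.0, burst_ibi_cv=0.4)
        s = simulate_culture(cfg)
        gt = s.ground_truth
        exp_bg = 0.5 * 1200 * 60
        assert abs(gt.n_background_spikes - exp_bg) < 3 * np.sqrt(exp_bg)
        n_bursts = gt.n_bursts
        exp_bursts = 1200 / 12.0
        assert abs(n_bursts - exp_bursts) < 3.5 * 0.4 * np.sqrt(exp_bursts)
        durs = (gt.burst_offsets - gt.burst_onsets)[~gt.truncated]
        se = cfg.burst_duration_cv * cfg.burst_duration_mean / np.sqrt(durs.size)
        assert abs(durs.mean() - cfg.burst_duration_mean) < 3.5 * se

    def test_truncation_recorded(self):
        # long bursts relative to the recording make end-truncation likely
        cfg = SimulationConfig(seed=1, duration=21.0, burst_ibi_mean=4.0,
                               burst_ibi_cv=0.1, burst_duration_mean=3.0,
                               burst_duration_cv=0.0, background_rate=0.0)
        s = simulate_culture(cfg)
        gt = s.ground_truth
        assert np.all(gt.burst_offsets <= 21.0)
        if gt.truncated.any():
            assert gt.burst_offsets[gt.truncated][-1] == 21.0

    def test_short_duration_warns_not_fails(self):
        cfg = SimulationConfig(seed=0, duration=5.0, burst_ibi_mean=10.0,
                               burst_duration_mean=0.3)
        with pytest.warns(UserWarning, match="shorter than the mean"):
            s = simulate_culture(cfg)
        assert s.ground_truth.warning is not None

    @pytest.mark.parametrize("bad", [
        dict(participation_prob=1.5),
        dict(background_rate=-1.0),
        dict(burst_ibi_mean=0.2, burst_duration_mean=0.5),
        dict(within_burst_envelope="sawtooth"),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)


class TestSimulateStudy:
    def test_bookkeeping_and_subseeds(self):
        recs = simulate_study(default_presets(), 3, seed=1)
        assert len(recs) == 2 * 4 * 3
        keys = {(r.condition, r.culture_id, r.div) for r in recs}
        assert len(keys) == 24
        seeds = {child_seed(1, c, i, d) for c in (CONTROL, DEFICIENT)
                 for i in range(3) for d in (10, 13, 15, 17)}
        assert len(seeds) == 24

    def test_same_master_seed_reproduces(self):
        a = simulate_study(default_presets(), 2, seed=9)
        b = simulate_study(default_presets(), 2, seed=9)
        for ra, rb in zip(a, b):
            assert ra.culture_id == rb.culture_id and ra.div == rb.div
            for eid in ra.trains:
                np.testing.assert_array_equal(ra.trains[eid], rb.trains[eid])

    def test_single_culture_per_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_study(default_presets(), 1, seed=0)

    def test_deficient_div13_fewer_planted_bursts(self):
        presets = {k: v for k, v in default_presets().items() if k[1] == 13}
        recs = simulate_study(presets, 8, seed=4)
        rate = {c: np.mean([r.ground_truth.n_bursts for r in recs
                            if r.condition == c]) for c in (CONTROL, DEFICIENT)}
        # configured burst-rate multiplier is 0.6
        assert rate[DEFICIENT] < rate[CONTROL]
        assert rate[DEFICIENT] / rate[CONTROL] == pytest.approx(0.6, abs=0.12)

    def test_preset_invariants(self):
        p = default_presets()
        assert (p[(DEFICIENT, 13)].config.background_rate
                < p[(CONTROL, 13)].config.background_rate)
        assert (1 / p[(DEFICIENT, 13)].config.burst_ibi_mean
                < 1 / p[(CONTROL, 13)].config.burst_ibi_mean)
        assert (p[(DEFICIENT, 17)].config.burst_ibi_cv
                > p[(CONTROL, 17)].config.burst_ibi_cv)


class TestSynthesizeRaw:
    def test_constant_offset_no_sources(self):
        s = simulate_culture(SimulationConfig(
            n_electrodes=2, duration=1.0, background_rate=0.0,
            participation_prob=0.0, seed=0))
        rec = synthesize_raw(s, noise_sd=0.0, dc_offset=3.0)
        np.testing.assert_allclose(rec.voltage, 3.0)

    def test_noise_median_absolute_value(self):
        # Gaussian sd 2 uV: median(|x|) = 0.6745 * sd = 1.349 uV
        s = simulate_culture(SimulationConfig(
            n_electrodes=4, duration=10.0, background_rate=0.0,
            participation_prob=0.0, seed=0))
        rec = synthesize_raw(s, noise_sd=2.0, seed=3)
        med = np.median(np.abs(rec.voltage))
        assert med == pytest.approx(2.0 * 0.6745, rel=0.02)

    def test_planted_spikes_recovered_end_to_end(self):
        from meanet import SpikeTrainSet

        trains = {0: np.linspace(0.5, 9.5, 10)}
        s = SpikeTrainSet(trains=trains, duration=10.0)
        rec = synthesize_raw(s, waveform_amplitude=50.0, noise_sd=2.0, seed=1)
        detected = detect_spikes(rec, DetectionParams())
        t = detected.trains[0]
        matched = sum(np.min(np.abs(t - plant)) < 0.001
                      for plant in trains[0])
        assert matched >= 9
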