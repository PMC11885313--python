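"""Generator correctness: determinism, config validation, planted structure."""

import numpy as np
import pandas as pd
import pytest

from strokesig.events import EVENT_COLUMNS
from strokesig.session import load_session, save_session
from strokesig.synthetic import (
    ConfigError,
    SyntheticConfig,
    generate_aperture_trace,
    generate_arat_session,
    generate_kinarm_session,
    generate_lfp,
    generate_spike_trains,
    generate_sync_pair,
)


class TestConfigValidation:
    def test_zero_duration_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(duration_s=0.0).validate()

    def test_pac_strength_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(pac_strength=1.2).validate()

    def test_beta_list_length_must_match_arrays(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_arrays=2, aperiodic_beta_per_array=(2.0,)).validate()

    def test_negative_tuning_depth_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(tuning_depth=-0.5).validate()

    def test_unknown_gamma_array_label_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(gamma_arrays=("Q9",)).validate()

    def test_schedule_too_long_for_duration_rejected(self):
        with pytest.raises(ConfigError):
            generate_aperture_trace(SyntheticConfig(duration_s=10.0, n_clean_closings=10))


class TestApertureBookkeeping:
    def test_clean_schedule_plants_paired_events(self):
        cfg = SyntheticConfig(duration_s=60.0, n_clean_closings=5, inter_block_hold_s=3.0)
        ap, events = generate_aperture_trace(cfg)
        assert len(events) == 10
        assert (events.event_type == "close").sum() == 5
        assert (events.event_type == "open").sum() == 5
        assert ap.min() >= 0.0 and ap.max() <= 100.0

    def test_pause_resume_onset_is_at_resumption(self):
        cfg = SyntheticConfig(
            duration_s=40.0, n_clean_closings=0, n_pause_resume=1, aperture_noise=0.0
        )
        ap, events = generate_aperture_trace(cfg)
        close = events[events.event_type == "close"].iloc[0]
        fs = 20.0
        i0 = int(round(close.onset_s * fs))
        # trace holds at 50% immediately before the marked onset and falls after
        assert ap[i0] == pytest.approx(50.0, abs=1.0)
        assert ap[i0 - 5] == pytest.approx(50.0, abs=1.0)
        assert ap[int(round(close.end_s * fs))] == pytest.approx(0.0, abs=1.0)


class TestDeterminism:
    def test_same_config_bit_identical_session(self):
        cfg = SyntheticConfig(
            n_arrays=1, channels_per_array=2, duration_s=40.0, n_clean_closings=2,
            inter_block_hold_s=3.0, n_responsive=2, seed=11,
        )
        b1, t1 = generate_arat_session(cfg)
        b2, t2 = generate_arat_session(cfg)
        np.testing.assert_array_equal(b1.lfp, b2.lfp)
        np.testing.assert_array_equal(b1.aperture, b2.aperture)
        for s1, s2 in zip(b1.spikes, b2.spikes):
            np.testing.assert_array_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.planted_events, t2.planted_events)
        assert t1.responsive_channel_ids == t2.responsive_channel_ids


class TestLFP:
    def test_gain_one_no_pac_is_pure_background(self):
        cfg = SyntheticConfig(
            n_arrays=1, channels_per_array=1, duration_s=20.0, gamma_event_gain=1.0,
            pac_strength=0.0, seed=2,
        )
        ev = pd.DataFrame(
            [["close", 10.0, 10.5, 100.0, 0.0, "reached_full_close"]], columns=EVENT_COLUMNS
        )
        with_events = generate_lfp(cfg, ev)
        without = generate_lfp(cfg, pd.DataFrame(columns=EVENT_COLUMNS))
        np.testing.assert_array_equal(with_events, without)

    def test_event_gamma_raises_high_band_power_around_closings(self):
        from strokesig.spectral import mean_band_power, sliding_psd

        cfg = SyntheticConfig(
            n_arrays=1, channels_per_array=2, duration_s=40.0, gamma_event_gain=8.0, seed=4
        )
        ev = pd.DataFrame(
            [["close", 20.0, 20.8, 100.0, 0.0, "reached_full_close"]], columns=EVENT_COLUMNS
        )
        lfp = generate_lfp(cfg, ev)
        series = sliding_psd(lfp.astype(float), cfg.fs_lfp, 1.0, 0.5, (100, 500), 1.0)
        times, feat = mean_band_power(series)
        during = feat[(times > 20.0) & (times < 21.0)].mean()
        before = feat[times < 19.0].mean()
        assert during > 4 * before
        # baseline feature sits in the decoder's open range
        assert 0.5 < before < 3.0

    def test_unknown_event_times_rejected(self):
        cfg = SyntheticConfig(n_arrays=1, channels_per_array=1, duration_s=10.0)
        ev = pd.DataFrame(
            [["close", 50.0, 50.5, 100.0, 0.0, "reached_full_close"]], columns=EVENT_COLUMNS
        )
        with pytest.raises(ConfigError):
            generate_lfp(cfg, ev)


class TestSpikes:
    def test_homogeneous_rate_recovered(self):
        cfg = SyntheticConfig(
            n_arrays=1, channels_per_array=4, duration_s=100.0, baseline_rate=10.0,
            burst_rate_per_min=0.0, n_responsive=0, seed=5,
        )
        spikes, responsive = generate_spike_trains(cfg, pd.DataFrame(columns=EVENT_COLUMNS))
        assert responsive == set()
        rates = [len(s) / 100.0 for s in spikes]
        assert np.mean(rates) == pytest.approx(10.0, rel=0.05)

    def test_spike_times_strictly_increasing(self, small_arat):
        _, bundle, _ = small_arat
        for st in bundle.spikes:
            assert np.all(np.diff(st) > 0)

    def test_responsive_channels_ramp_before_closing(self, small_arat):
        _, bundle, truth = small_arat
        closes = truth.planted_events.query("event_type == 'close'").onset_s.to_numpy()
        resp = sorted(truth.responsive_channel_ids)[0]
        nonresp = next(i for i in range(len(bundle.spikes)) if i not in truth.responsive_channel_ids)
        def pre_rate(ch):
            st = bundle.spikes[ch]
            return np.mean(
                [np.sum((st >= t - 1.0) & (st < t)) for t in closes]
            )
        assert pre_rate(resp) > 2 * pre_rate(nonresp)

    def test_no_bursts_no_excess_coincidence(self):
        cfg = SyntheticConfig(
            n_arrays=1, channels_per_array=16, duration_s=60.0, burst_rate_per_min=0.0,
            n_responsive=0, seed=6,
        )
        spikes, _ = generate_spike_trains(cfg, pd.DataFrame(columns=EVENT_COLUMNS))
        edges = np.arange(0, 60.0 + 0.05, 0.05)
        counts = np.stack([np.histogram(s, edges)[0] for s in spikes])
        pop = counts.sum(axis=0)
        # population count dispersion consistent with independent Poisson trains
        assert pop.var() / pop.mean() < 1.5

    def test_bursts_create_coordinated_excess(self):
        cfg = SyntheticConfig(
            n_arrays=1, channels_per_array=16, duration_s=60.0, burst_rate_per_min=10.0,
            burst_gain=8.0, n_responsive=0, seed=6,
        )
        spikes, _ = generate_spike_trains(cfg, pd.DataFrame(columns=EVENT_COLUMNS))
        edges = np.arange(0, 60.0 + 0.05, 0.05)
        pop = np.stack([np.histogram(s, edges)[0] for s in spikes]).sum(axis=0)
        assert pop.var() / pop.mean() > 2.0


class TestKinarm:
    def test_24_movements_three_per_direction(self):
        cfg = SyntheticConfig(n_trials_per_direction=3, seed=0)
        trials, spikes, pref, depth = generate_kinarm_session(cfg)
        assert len(trials) == 24
        assert (trials.appear_s < trials.reach_s).all()
        assert np.bincount(trials.direction, minlength=8).tolist() == [3] * 8

    def test_tuned_channels_marked_in_truth(self):
        cfg = SyntheticConfig(n_tuned=10, seed=1)
        _, _, pref, depth = generate_kinarm_session(cfg)
        assert (depth > 0).sum() == 10
        assert np.isnan(pref[depth == 0]).all()

    def test_zero_trials_rejected(self):
        with pytest.raises(ConfigError):
            generate_kinarm_session(SyntheticConfig(n_trials_per_direction=0))


class TestSync:
    def test_planted_lag_recovered(self):
        from strokesig.preprocess import align_streams

        cfg = SyntheticConfig(
            n_arrays=1, channels_per_array=1, duration_s=30.0, stream_lag_s=0.5, seed=8
        )
        a, b, lag = generate_sync_pair(cfg)
        assert lag == 0.5
        est = align_streams(a, b, cfg.fs_lfp)
        assert est == pytest.approx(0.5, abs=1.5 / cfg.fs_lfp)


class TestSessionIO:
    def test_hdf5_roundtrip(self, tmp_path, small_arat):
        _, bundle, _ = small_arat
        path = tmp_path / "session.h5"
        save_session(bundle, path)
        back = load_session(path)
        np.testing.assert_allclose(back.lfp, bundle.lfp)
        np.testing.assert_array_equal(back.aperture, bundle.aperture)
        assert back.channel_array == bundle.channel_array
        for s1, s2 in zip(back.spikes, bundle.spikes):
            np.testing.assert_array_equal(s1, s2)
        assert back.duration_s == bundle.duration_s

    def test_kinarm_roundtrip(self, tmp_path):
        from strokesig.synthetic import generate_kinarm_bundle

        cfg = SyntheticConfig(n_arrays=1, channels_per_array=4, n_tuned=2, seed=9)
        bundle, truth = generate_kinarm_bundle(cfg)
        path = tmp_path / "kin.h5"
        save_session(bundle, path)
        back = load_session(path)
        pd.testing.assert_frame_equal(
            back.kinarm_trials.astype(bundle.kinarm_trials.dtypes),
            bundle.kinarm_trials,
        )

    def test_ground_truth_json(self, tmp_path, small_arat):
        from strokesig.session import save_ground_truth
        import json

        _, _, truth = small_arat
        path = tmp_path / "truth.json"
        save_ground_truth(truth, path)
        data = json.loads(path.read_text())
        assert len(data["planted_events"]) == len(truth.planted_events)
        assert data["responsive_channel_ids"] == sorted(truth.responsive_channel_ids)
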