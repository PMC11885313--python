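"""Phase-amplitude coupling: analytic-signal extraction, phase binning, and
the KL-distance modulation index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strokesig.pac import (
    bin_amplitude_by_phase,
    event_locked_pac,
    instantaneous_amplitude,
    instantaneous_phase,
    modulation_index,
    sliding_pac,
)

FS = 1000.0


def _sine(freq, dur=10.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestAnalyticSignal:
    def test_phase_advances_linearly_and_wraps(self):
        x, t = _sine(2.5)
        ph = instantaneous_phase(x, FS, (1, 4))
        core = slice(int(FS), int(9 * FS))
        dph = np.diff(np.unwrap(np.radians(ph[core])))
        assert np.degrees(dph.mean()) * FS / 360 == pytest.approx(2.5, rel=0.01)
        assert ph.min() >= -180.0 and ph.max() < 180.0

    def test_cosine_peak_has_zero_phase(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.cos(2 * np.pi * 2.5 * t)
        ph = instantaneous_phase(x, FS, (1, 4))
        peaks = np.flatnonzero(np.abs(t - np.round(t * 2.5) / 2.5) < 1e-9)
        peaks = peaks[(peaks > FS) & (peaks < 9 * FS)]
        assert np.abs(ph[peaks]).max() < 5.0

    def test_constant_signal_phase_undefined(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.ones(1000), FS, (1, 4))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_amplitude(np.random.default_rng(0).standard_normal(1000), FS, (100, 600))

    def test_envelope_of_pure_tone(self):
        x, _ = _sine(100.0, amp=2.0)
        env = instantaneous_amplitude(x, FS, (70, 450))
        core = env[int(FS) : int(9 * FS)]
        assert core.mean() == pytest.approx(2.0, rel=0.05)

    def test_am_modulation_recovered(self):
        t = np.arange(int(10 * FS)) / FS
        x = (1 + 0.5 * np.cos(2 * np.pi * 2.0 * t)) * np.sin(2 * np.pi * 150.0 * t)
        env = instantaneous_amplitude(x, FS, (70, 450))
        core = slice(int(FS), int(9 * FS))
        expected = 1 + 0.5 * np.cos(2 * np.pi * 2.0 * t[core])
        assert np.corrcoef(env[core], expected)[0, 1] > 0.99

    def test_zero_signal_zero_envelope(self):
        env = instantaneous_amplitude(np.zeros(2000), FS, (70, 450))
        np.testing.assert_allclose(env, 0.0, atol=1e-12)


class TestBinning:
    def test_uniform_phase_constant_amplitude_gives_flat_p(self, rng):
        phase = rng.uniform(-180, 180, 100_000)
        dist = bin_amplitude_by_phase(phase, np.full(phase.size, 3.0), 20)
        np.testing.assert_allclose(dist.p, 1 / 20, atol=1e-12)
        np.testing.assert_allclose(dist.mean_amplitude, 3.0)

    def test_one_plus_cos_matches_bin_integrals(self, rng):
        phase = rng.uniform(-180, 180, 2_000_000)
        amp = 1 + np.cos(np.radians(phase))
        dist = bin_amplitude_by_phase(phase, amp, 20)
        edges = np.radians(dist.edges_deg)
        # mean of 1+cos over each bin, normalized
        means = np.array(
            [
                1 + (np.sin(b) - np.sin(a)) / (b - a)
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
        np.testing.assert_allclose(dist.p, means / means.sum(), rtol=0.01)

    def test_all_samples_in_one_bin_gives_indicator(self):
        dist = bin_amplitude_by_phase(np.full(100, 10.0), np.ones(100), 20)
        expected = np.zeros(20)
        expected[np.digitize(10.0, dist.edges_deg) - 1] = 1.0
        np.testing.assert_allclose(dist.p, expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bin_amplitude_by_phase(np.zeros(5), np.zeros(6))

    def test_sorting_oracle_agreement(self, rng):
        # histogram-free oracle: sort by phase, group by bin membership
        phase = rng.uniform(-180, 180, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        dist = bin_amplitude_by_phase(phase, amp, 20)
        order = np.argsort(phase)
        ps, As = phase[order], amp[order]
        bins = np.floor((ps + 180) / 18).astype(int).clip(0, 19)
        means = np.array([As[bins == i].mean() if (bins == i).any() else 0.0 for i in range(20)])
        np.testing.assert_allclose(dist.p, means / means.sum(), atol=1e-12)


class TestModulationIndex:
    def test_uniform_distribution_gives_zero(self):
        assert modulation_index(np.full(20, 1 / 20)) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_gives_one(self):
        p = np.zeros(20)
        p[7] = 1.0
        assert modulation_index(p) == pytest.approx(1.0)

    def test_one_plus_cos_matches_entropy_oracle(self, rng):
        phase = rng.uniform(-180, 180, 1_000_000)
        amp = 1 + np.cos(np.radians(phase))
        dist = bin_amplitude_by_phase(phase, amp, 20)
        p = dist.p
        h = -sum(pi * np.log(pi) for pi in p if pi > 0)
        expected = (np.log(20) - h) / np.log(20)
        assert modulation_index(dist) == pytest.approx(expected, abs=1e-12)

    def test_zero_sum_distribution_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(np.zeros(20))

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_amplitude_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-180, 180, 4000)
        amp = rng.gamma(2.0, 1.0, 4000)
        mi1 = modulation_index(bin_amplitude_by_phase(phase, amp))
        mi2 = modulation_index(bin_amplitude_by_phase(phase, c * amp))
        assert mi1 == pytest.approx(mi2, rel=1e-9)

    @given(st.integers(0, 10_000))
    def test_mi_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(20)
        mi = modulation_index(p)
        assert 0.0 <= mi <= 1.0


class TestCoupledSignals:
    @staticmethod
    def _coupled(strength, seed, dur=30.0, fs=2000.0):
        from strokesig.synthetic import SyntheticConfig, generate_lfp
        import pandas as pd
        from strokesig.events import EVENT_COLUMNS

        cfg = SyntheticConfig(
            n_arrays=1,
            channels_per_array=1,
            duration_s=dur,
            pac_strength=strength,
            gamma_event_gain=1.0,
            seed=seed,
        )
        return generate_lfp(cfg, pd.DataFrame(columns=EVENT_COLUMNS))[0].astype(float), fs

    def test_coupled_channel_exceeds_uncoupled(self):
        x0, fs = self._coupled(0.0, 5)
        x1, _ = self._coupled(1.0, 5)
        onsets = np.arange(2.0, 28.0, 2.0)
        mi0 = event_locked_pac(x0, fs, onsets)[0]
        mi1 = event_locked_pac(x1, fs, onsets)[0]
        assert mi1 > 5 * mi0

    def test_surrogate_control_separates_strengths(self, rng):
        x1, fs = self._coupled(1.0, 6)
        phase = instantaneous_phase(x1, fs)
        amp = instantaneous_amplitude(x1, fs)
        mi = modulation_index(bin_amplitude_by_phase(phase, amp))
        null = []
        for _ in range(20):
            shift = int(rng.integers(fs, x1.size - fs))
            null.append(modulation_index(bin_amplitude_by_phase(np.roll(phase, shift), amp)))
        assert mi > np.quantile(null, 0.95)

    def test_sliding_pac_flags_short_windows(self):
        x, fs = self._coupled(0.5, 7, dur=10.0)
        with pytest.warns(UserWarning):
            series = sliding_pac(x, fs, window_s=1.0)
        assert series.low_confidence
        assert series.mi.min() >= 0.0 and series.mi.max() <= 1.0
        # 1-s windows, 80% overlap → one MI every 0.2 s
        assert series.times[1] - series.times[0] == pytest.approx(0.2)
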