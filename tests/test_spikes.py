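"""Firing rates, Kruskal–Wallis responsiveness, NLIFR, neuromodulation index."""

import numpy as np
import pytest
from scipy import stats

from strokesig.spikes import (
    binned_firing_rates,
    kw_responsiveness,
    kw_test,
    neuromodulation_index,
    nlifr_from_spikes,
    select_characterization_window,
)


def kw_oracle(*groups):
    """Brute-force rank-based Kruskal–Wallis with tie correction."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0:
        return 0.0, 1.0
    h /= tie
    p = stats.chi2.sf(h, len(groups) - 1)
    return h, p


class TestBinnedRates:
    def test_uniform_spikes_give_constant_rate(self):
        epochs = [[np.arange(0.05, 1.0, 0.1) - 0.5]]  # 10 spikes over (-0.5, 0.5)
        starts, rates = binned_firing_rates(epochs, 0.1, 0.02, (-0.5, 0.5))
        assert rates.mean() == pytest.approx(10.0, rel=0.15)

    def test_no_spikes_all_zero(self):
        epochs = [[np.empty(0), np.empty(0)]]
        _, rates = binned_firing_rates(epochs, 0.1, 0.02, (-1, 1))
        assert not rates.any()

    def test_window_count_formula(self):
        epochs = [[np.empty(0)]]
        starts, rates = binned_firing_rates(epochs, 0.1, 0.02, (-1.0, 1.0))
        assert rates.shape[-1] == 96  # floor((2-0.1)/0.02)+1

    def test_empty_epoch_set_rejected(self):
        with pytest.raises(ValueError):
            binned_firing_rates([], 0.1, 0.02)


class TestKruskalWallis:
    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_rank_oracle_small_samples(self, trial):
        rng = np.random.default_rng(trial)
        sizes = rng.integers(2, 7, size=rng.integers(2, 4))
        if sizes.sum() > 12:
            sizes = sizes[:2]
        # integer-valued samples force ties
        groups = [rng.integers(0, 4, s).astype(float) for s in sizes]
        h0, p0 = kw_oracle(*groups)
        h1, p1 = kw_test(*groups)
        assert h1 == pytest.approx(h0, abs=1e-10)
        assert p1 == pytest.approx(p0, abs=1e-10)

    def test_strong_difference_flagged(self):
        rng = np.random.default_rng(0)
        close = rng.poisson(2.0, size=(1, 19, 5)) / 0.1  # ~20 spikes/s
        open_ = rng.poisson(0.2, size=(1, 21, 5)) / 0.1  # ~2 spikes/s
        report = kw_responsiveness(close.astype(float), open_.astype(float), 0.01)
        assert report.flags[0].all()

    def test_null_flag_rate_near_alpha(self):
        # quick version of the level check (the acceptance suite runs 10^4)
        rng = np.random.default_rng(1)
        close = rng.poisson(1.0, size=(64, 19, 20)).astype(float)
        open_ = rng.poisson(1.0, size=(64, 21, 20)).astype(float)
        report = kw_responsiveness(close, open_, 0.01)
        rate = report.flags.mean()
        assert 0.002 < rate < 0.025

    def test_alpha_zero_flags_nothing(self):
        rng = np.random.default_rng(2)
        r = rng.poisson(1.0, size=(8, 5, 4)).astype(float)
        report = kw_responsiveness(r, r + rng.poisson(3.0, r.shape), alpha=0.0)
        assert not report.flags.any()

    def test_all_tied_samples_give_p_one(self):
        h, p = kw_test(np.zeros(5), np.zeros(6))
        assert (h, p) == (0.0, 1.0)


class TestCharacterizationWindow:
    def test_max_count_window_selected(self):
        p = np.ones((10, 6))
        p[:7, 3] = 0.001  # 7 channels significant at window 3
        p[:2, 1] = 0.001
        from strokesig.spikes import ResponsivenessReport

        report = ResponsivenessReport(
            window_starts=np.arange(6.0), statistic=np.zeros_like(p), p_value=p,
            alpha=0.01, window_s=0.1,
        )
        idx, responsive = select_characterization_window(report)
        assert idx == 3
        assert responsive.tolist() == list(range(7))

    def test_single_responsive_channel(self):
        from strokesig.spikes import ResponsivenessReport

        p = np.ones((4, 5))
        p[2, 4] = 1e-5
        report = ResponsivenessReport(np.arange(5.0), np.zeros_like(p), p, 0.01, 0.1)
        idx, responsive = select_characterization_window(report)
        assert idx == 4 and responsive.tolist() == [2]

    def test_null_gives_empty_or_tiny_set(self):
        rng = np.random.default_rng(3)
        close = rng.poisson(1.0, size=(32, 10, 12)).astype(float)
        open_ = rng.poisson(1.0, size=(32, 10, 12)).astype(float)
        report = kw_responsiveness(close, open_, 0.01)
        _, responsive = select_characterization_window(report)
        assert responsive.size <= 4


class TestNLIFR:
    def test_constant_rate_reaches_one_at_segment_max(self):
        spikes = [np.arange(0.0, 30.0, 0.05)]  # 20 spikes/s
        times, nl = nlifr_from_spikes(spikes, 15.0, (-0.5, 1.0))
        assert nl.max() == pytest.approx(1.0)
        # steady state: late samples all near the max
        assert nl[0, -10:].min() > 0.8

    def test_single_spike_impulse_decays_with_tau(self):
        spikes = [np.array([10.0])]
        times, nl = nlifr_from_spikes(
            spikes, 10.0, (0.0, 2.0), window_s=0.02, step_s=0.02, tau_s=0.3
        )
        peak_idx = nl[0].argmax()
        later = peak_idx + 15  # 0.3 s later
        expected = np.exp(-15 * 0.02 / 0.3)
        assert nl[0, later] / nl[0, peak_idx] == pytest.approx(expected, rel=0.05)

    def test_rate_scaling_invariance(self):
        base = np.arange(0.2, 20.0, 0.2)
        doubled = np.sort(np.concatenate([base, base + 0.01]))
        _, nl = nlifr_from_spikes([base, doubled], 10.0, (-0.5, 1.0))
        np.testing.assert_allclose(nl[0], nl[1], atol=0.02)

    def test_silent_channel_stays_zero(self):
        _, nl = nlifr_from_spikes([np.empty(0)], 5.0, (-0.5, 1.0))
        assert not nl.any()

    def test_values_within_unit_interval(self, small_arat):
        _, bundle, _ = small_arat
        _, nl = nlifr_from_spikes(bundle.spikes, 30.0, (-0.5, 1.0))
        assert nl.min() >= 0.0 and nl.max() <= 1.0


class TestNeuromodulationIndex:
    @pytest.mark.parametrize("seed", range(5))
    def test_bursting_channel_outranks_constant(self, seed):
        rng = np.random.default_rng(seed)
        dur = 60.0
        constant = np.sort(rng.uniform(0, dur, int(10 * dur)))
        bursty = []
        for t0 in np.arange(1.0, dur, 3.0):
            bursty.append(rng.uniform(t0, t0 + 0.2, 30))
        bursty = np.sort(np.concatenate(bursty))
        scores, top = neuromodulation_index([constant, bursty], dur, top_k=1)
        assert scores[1] > scores[0]
        assert top.tolist() == [1]

    def test_deterministic_spacing_scores_near_zero(self):
        regular = np.arange(0.005, 60.0, 0.05)  # exactly 1 spike per 50-ms bin
        scores, _ = neuromodulation_index([regular], 60.0)
        assert scores[0] == pytest.approx(0.0, abs=1e-9)

    def test_top_k_equal_channel_count_returns_all(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(0, 10, 50)) for _ in range(5)]
        _, top = neuromodulation_index(spikes, 10.0, top_k=5)
        assert sorted(top.tolist()) == [0, 1, 2, 3, 4]

    def test_silent_channel_scores_zero(self):
        scores, _ = neuromodulation_index([np.empty(0)], 10.0)
        assert scores[0] == 0.0
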