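"""STFT power and the ERDd distribution-overlap score."""
import numpy as np
import pytest
from scipy.fft import rfft
from scipy.signal.windows import hann
from scipy.stats import norm

from smrpipe.erdd import (FeatureBand, band_power, erdd_profile, erdd_score,
                          select_feature_bands, stft_power)

FS = 500.0


def _tone(freq, n=3000, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS)


def _hist_tv(a, b, bins=100):
    """Histogram total-variation oracle on a shared log-scale grid."""
    la, lb = np.log(a), np.log(b)
    lo, hi = min(la.min(), lb.min()), max(la.max(), lb.max())
    grid = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(la, bins=grid, density=False)
    pb, _ = np.histogram(lb, bins=grid, density=False)
    return 0.5 * np.abs(pa / len(la) - pb / len(lb)).sum()


class TestSTFTPower:
    def test_zero_signal(self):
        ps = stft_power(np.zeros((1, 1, 3000)))
        assert np.all(ps.power == 0)
        assert ps.freqs[1] - ps.freqs[0] == pytest.approx(1.0)

    def test_tone_concentrated_and_matches_dft_oracle(self):
        ps = stft_power(_tone(10.0)[None, None, :])
        total = ps.power.sum()
        near = ps.power[0, 0, :, 9:12].sum()
        assert near / total > 0.90
        # exact single-frame oracle: Hann-windowed DFT of the first frame
        frame = _tone(10.0)[:500] * hann(500, sym=False)
        oracle = np.abs(rfft(frame)) ** 2
        assert ps.power[0, 0, 0, :49] == pytest.approx(oracle[:49], abs=1e-6)

    def test_tone_powers_additive(self):
        p1 = stft_power(_tone(10.0)[None, None, :]).power
        p2 = stft_power(_tone(20.0)[None, None, :]).power
        p12 = stft_power((_tone(10.0) + _tone(20.0))[None, None, :]).power
        tot = p12.sum()
        assert abs(p12.sum() - (p1.sum() + p2.sum())) < 0.02 * tot

    def test_frame_grid(self):
        ps = stft_power(np.zeros((1, 1, 3000)))
        assert ps.frame_starts[0] == 0.0
        assert ps.frame_starts[1] == pytest.approx(0.1)
        assert ps.frame_starts[-1] == pytest.approx(5.0)
        inside = ps.frames_in((2.0, 6.0))
        assert ps.frame_starts[inside][0] == pytest.approx(2.0)
        assert ps.frame_starts[inside][-1] == pytest.approx(5.0)

    def test_short_trial_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            stft_power(np.zeros((1, 1, 300)))


class TestErddScore:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.standard_normal(500))
        assert erdd_score(x, x) == 0.0

    def test_disjoint_supports_saturate(self):
        rng = np.random.default_rng(1)
        lo = np.exp(rng.standard_normal(2000) - 20)
        hi = np.exp(rng.standard_normal(2000) + 20)
        assert erdd_score(lo, hi) == pytest.approx(-100.0, abs=2.0)
        assert erdd_score(hi, lo) == pytest.approx(100.0, abs=2.0)

    def test_lognormal_shift_matches_gaussian_tv(self):
        """LogNormal(0,1) vs LogNormal(1,1): TV = 2*Phi(1/2) - 1."""
        rng = np.random.default_rng(2)
        a = np.exp(rng.standard_normal(100_000))
        r = np.exp(1.0 + rng.standard_normal(100_000))
        expected = -100.0 * (2.0 * norm.cdf(0.5) - 1.0)
        assert erdd_score(a, r) == pytest.approx(expected, abs=1.0)

    def test_antisymmetry_and_range(self):
        rng = np.random.default_rng(3)
        for delta in (0.2, 1.0, 4.0):
            a = np.exp(rng.standard_normal(2000))
            b = np.exp(delta + rng.standard_normal(2000))
            s = erdd_score(a, b)
            assert -100.0 <= s <= 100.0
            assert erdd_score(b, a) == pytest.approx(-s, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.standard_normal(3000))
        b = np.exp(0.7 + rng.standard_normal(3000))
        assert erdd_score(37.0 * a, 37.0 * b) == pytest.approx(
            erdd_score(a, b), abs=0.5)

    def test_matches_histogram_tv_oracle(self):
        rng = np.random.default_rng(5)
        a = np.exp(0.3 * rng.standard_normal(4000))
        b = np.exp(0.8 + 0.5 * rng.standard_normal(4000))
        assert abs(erdd_score(a, b)) == pytest.approx(
            100 * _hist_tv(a, b), abs=3.0)

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(6)
        base = np.exp(rng.standard_normal(5000))
        scores = [abs(erdd_score(np.exp(d + rng.standard_normal(5000)), base))
                  for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            erdd_score(np.array([]), np.ones(30))
        with pytest.raises(ValueError, match="positive"):
            erdd_score(np.zeros(30), np.ones(30))
        with pytest.warns(UserWarning, match="fewer than 20"):
            erdd_score(np.ones(5) * 2, np.ones(30) * 3.0)


class TestErddScoreProperties:
    """Hypothesis-driven invariants of the score."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(shift=st.floats(-3.0, 3.0), scale=st.floats(0.2, 3.0),
           seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_range_antisymmetry_and_sign(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a = np.exp(shift + scale * rng.standard_normal(400))
        b = np.exp(rng.standard_normal(400))
        s = erdd_score(a, b)
        assert -100.0 <= s <= 100.0
        assert erdd_score(b, a) == pytest.approx(-s, abs=1e-9)
        if shift < -0.5:
            assert s < 0  # clearly lower active power: ERD sign
        if shift > 0.5:
            assert s > 0

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_feature_band_contains_peak_above_threshold(self, seed):
        rng = np.random.default_rng(seed)
        profile = rng.uniform(-80, 20, size=(1, 49))
        freqs = np.arange(49.0)
        bands = select_feature_bands(profile, freqs)
        for fb in bands:
            lo, hi = int(fb.band[0]), int(fb.band[1])
            assert lo <= fb.peak_freq <= hi
            segment = profile[fb.component, lo:hi + 1]
            assert np.all(np.abs(segment) >= 0.30 * abs(fb.peak_score))
            assert np.all(np.sign(segment) == np.sign(fb.peak_score))


class TestErddProfile:
    def test_identical_conditions_score_near_zero(self):
        """Null data: scores shrink toward 0 (KDE noise floor ~ n^-2/5)."""
        rng = np.random.default_rng(7)
        import pandas as pd
        # i.i.d. power samples at n=2000: the score itself is < 5
        null = erdd_score(np.exp(rng.standard_normal(2000)),
                          np.exp(rng.standard_normal(2000)))
        assert abs(null) < 5.0
        # profile over correlated (90 % overlap) windows, 80 trials/side
        power = stft_power(rng.standard_normal((160, 1, 3000)),
                           trial_info=pd.DataFrame({
                               "condition": ["imagery"] * 80
                               + ["visual_attention"] * 80}))
        profile = erdd_profile(power)
        assert np.abs(profile).max() < 10.0
        assert np.abs(profile).mean() < 5.0

    def test_planted_band_is_most_negative(self, mu_session_filtered,
                                           mu_decomposition):
        from smrpipe.erdd import component_signals

        power = stft_power(
            component_signals(mu_session_filtered, mu_decomposition.W[:, :1]),
            trial_info=mu_session_filtered.trial_info)
        profile = erdd_profile(power)
        peak = np.argmin(profile[0])
        assert 8 <= power.freqs[peak] <= 14

    def test_missing_condition_rejected(self):
        import pandas as pd
        power = stft_power(np.random.default_rng(8).standard_normal(
            (4, 1, 3000)), trial_info=pd.DataFrame(
            {"condition": ["imagery"] * 4}))
        with pytest.raises(ValueError, match="both conditions"):
            erdd_profile(power)


class TestFeatureBands:
    FREQS = np.arange(0.0, 49.0)

    def _profile(self, scores_by_freq):
        profile = np.zeros((1, 49))
        for f, s in scores_by_freq.items():
            profile[0, int(f)] = s
        return profile

    def test_hand_traced_band_growth(self):
        profile = self._profile({9: -20, 10: -30, 11: -80, 12: -30, 13: -20})
        (fb,) = select_feature_bands(profile, self.FREQS)
        assert fb.band == (10.0, 12.0)
        assert fb.peak_freq == 11.0
        assert fb.peak_score == -80.0
        assert fb.polarity == "ERD"

    def test_single_bin_band(self):
        (fb,) = select_feature_bands(self._profile({15: -40}), self.FREQS)
        assert fb.band == (15.0, 15.0)

    def test_tie_breaks_to_lower_frequency(self):
        profile = self._profile({9: -50, 20: -50})
        (fb,) = select_feature_bands(profile, self.FREQS)
        assert fb.peak_freq == 9.0

    def test_polarity_restriction_and_empty(self):
        profile = self._profile({10: -50, 20: 60})
        erd = select_feature_bands(profile, self.FREQS, polarity="ERD")
        ers = select_feature_bands(profile, self.FREQS, polarity="ERS")
        assert erd[0].peak_freq == 10.0 and erd[0].polarity == "ERD"
        assert ers[0].peak_freq == 20.0 and ers[0].polarity == "ERS"
        assert select_feature_bands(np.zeros((1, 49)), self.FREQS) == []

    def test_same_sign_growth_stops_at_sign_flip(self):
        profile = self._profile({9: 40, 10: -30, 11: -80, 12: -30, 13: 40})
        (fb,) = select_feature_bands(profile, self.FREQS)
        assert fb.band == (10.0, 12.0)

    def test_band_power_averages_bins(self):
        import pandas as pd
        power = stft_power(np.random.default_rng(9).standard_normal(
            (2, 1, 3000)), trial_info=pd.DataFrame(
            {"condition": ["imagery"] * 2}))
        fb = FeatureBand(0, (10.0, 12.0), 11.0, -50.0, "ERD")
        bp = band_power(power, fb)
        direct = power.power[:, 0, :, 10:13].mean(axis=2)
        assert np.allclose(bp, direct)
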