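"""Wavelet family, band power, baseline normalization, binning, outliers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmndyn import spectral
from dmndyn.errors import ConfigurationError, ValidationError


class TestWaveletFamily:
    def test_default_family_count_and_endpoints(self):
        fam = spectral.build_wavelet_family()
        assert len(fam.center_freqs) == 100
        assert fam.center_freqs[0] == 1.0
        assert fam.center_freqs[-1] == 200.0

    def test_geometric_spacing_formula(self):
        fam = spectral.build_wavelet_family()
        assert fam.center_freqs[1] == pytest.approx(200.0 ** (1 / 99), rel=1e-12)
        ratios = fam.center_freqs[1:] / fam.center_freqs[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_two_frequency_family_is_endpoints(self):
        fam = spectral.build_wavelet_family(n_freqs=2)
        np.testing.assert_array_equal(fam.center_freqs, [1.0, 200.0])

    def test_temporal_sd_is_cycles_over_angular_frequency(self):
        fam = spectral.build_wavelet_family()
        assert fam.sigma_t(10.0) == pytest.approx(7.0 / (2 * np.pi * 10.0))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            spectral.build_wavelet_family(n_freqs=1)
        with pytest.raises(ConfigurationError):
            spectral.build_wavelet_family(f_min=10, f_max=5)


class TestTFDecompose:
    rate = 500.0

    def test_zero_signal_zero_magnitude(self):
        fam = spectral.build_wavelet_family().subset(4, 8)
        tf = spectral.tf_decompose(np.zeros(int(20 * self.rate)), self.rate, fam)
        assert np.allclose(tf, 0.0)

    def test_tone_argmax_at_nearest_center_frequency(self):
        fam = spectral.build_wavelet_family()
        t = np.arange(int(20 * self.rate)) / self.rate
        tf = spectral.tf_decompose(np.sin(2 * np.pi * 40.0 * t), self.rate, fam)
        profile = tf[:, 4000:6000].mean(axis=1)
        nearest = fam.center_freqs[np.argmin(np.abs(fam.center_freqs - 40.0))]
        assert fam.center_freqs[np.argmax(profile)] == nearest

    def test_linearity_in_amplitude(self):
        fam = spectral.build_wavelet_family().subset(30, 70)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(10 * self.rate))
        np.testing.assert_allclose(spectral.tf_decompose(3.5 * x, self.rate, fam),
                                   3.5 * spectral.tf_decompose(x, self.rate, fam),
                                   rtol=1e-9)

    def test_epoch_shorter_than_wavelet_rejected(self):
        fam = spectral.build_wavelet_family()  # includes 1 Hz
        with pytest.raises(ValidationError, match="shorter"):
            spectral.tf_decompose(np.zeros(1000), self.rate, fam)

    def test_matches_reference_morlet_implementation(self):
        """Cross-check against mne's Morlet transform: per-frequency magnitude
        time courses must be proportional (normalizations differ by a constant)."""
        mne = pytest.importorskip("mne")
        from mne.time_frequency import tfr_array_morlet
        t = np.arange(int(20 * self.rate)) / self.rate
        sig = np.sin(2 * np.pi * 6.0 * t) + 0.5 * np.sin(2 * np.pi * 45.0 * t)
        fam = spectral.build_wavelet_family().subset(4, 8)
        mine = spectral.tf_decompose(sig, self.rate, fam)
        theirs = np.abs(tfr_array_morlet(sig[None, None, :], self.rate,
                                         fam.center_freqs, n_cycles=fam.n_cycles,
                                         output="complex")[0, 0])
        interior = slice(3000, 7000)
        ratio = mine[:, interior] / theirs[:, interior]
        cv = ratio.std(axis=1) / ratio.mean(axis=1)
        assert cv.max() < 1e-3


class TestBandPower:
    def test_band_average_is_membership_mean(self):
        fam = spectral.build_wavelet_family()
        rng = np.random.default_rng(1)
        tf = rng.random((100, 50))
        out = spectral.band_power(tf, fam, spectral.THETA)
        sel = (fam.center_freqs >= 4) & (fam.center_freqs <= 8)
        np.testing.assert_allclose(out, tf[sel].mean(axis=0))

    def test_single_in_range_frequency_is_identity(self):
        fam = spectral.WaveletFamily(np.array([2.0, 6.0, 20.0]))
        tf = np.arange(30.0).reshape(3, 10)
        out = spectral.band_power(tf, fam, spectral.THETA)
        np.testing.assert_array_equal(out, tf[1])

    def test_all_ones_gives_unit_series(self):
        fam = spectral.build_wavelet_family()
        out = spectral.band_power(np.ones((100, 20)), fam, spectral.GAMMA)
        np.testing.assert_allclose(out, 1.0)

    def test_empty_band_rejected(self):
        fam = spectral.WaveletFamily(np.array([1.0, 100.0]))
        with pytest.raises(ConfigurationError, match="no centre frequency"):
            spectral.band_power(np.ones((2, 5)), fam, spectral.THETA)


class TestBaselineNormalize:
    times = np.arange(-1.0, 2.0, 0.01)

    def test_constant_series_is_zero_percent(self):
        out = spectral.baseline_normalize(np.full_like(self.times, 7.0), self.times)
        np.testing.assert_allclose(out, 0.0)

    def test_thirty_percent_step(self):
        series = np.where(self.times < 0, 1.0, 1.3)
        out = spectral.baseline_normalize(series, self.times)
        assert out[self.times > 0.1].mean() == pytest.approx(30.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(2)
        series = rng.random(self.times.size) + 0.5
        a = spectral.baseline_normalize(series, self.times)
        b = spectral.baseline_normalize(100.0 * series, self.times)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_nonpositive_baseline_excludes_trial(self):
        series = np.where(self.times < 0, 0.0, 1.0)
        with pytest.raises(ValidationError, match="baseline"):
            spectral.baseline_normalize(series, self.times)


class TestSlidingWindows:
    def test_default_scheme_29_bins_first_center_half_second(self):
        w = spectral.WindowSpec()
        assert w.n_bins == 29
        assert w.centers[0] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diff(w.centers), 0.5)

    @pytest.mark.parametrize("span,win,overlap,expected", [
        (15.0, 1.0, 0.5, 29), (1.0, 1.0, 0.5, 1), (10.0, 1.0, 0.5, 19),
        (15.0, 2.0, 0.5, 14), (15.0, 1.0, 0.0, 15),
    ])
    def test_bin_count_formula(self, span, win, overlap, expected):
        w = spectral.WindowSpec(0.0, span, win, overlap)
        assert w.n_bins == expected

    @given(span=st.floats(2.0, 40.0), win=st.floats(0.25, 2.0),
           overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bin_count_matches_closed_form(self, span, win, overlap):
        if span < win:
            return
        w = spectral.WindowSpec(0.0, span, win, overlap)
        step = win * (1 - overlap)
        assert w.n_bins == int(np.floor((span - win) / step + 1e-9)) + 1
        assert w.centers[0] == pytest.approx(win / 2)

    def test_window_longer_than_span_rejected(self):
        with pytest.raises(ConfigurationError):
            spectral.WindowSpec(0.0, 0.5, 1.0, 0.5)

    def test_bin_values_are_window_means(self):
        rate = 500.0
        times = np.arange(0, 15, 1 / rate)
        series = times.copy()  # linear ramp: window mean equals its center
        vals, centers = spectral.sliding_window_bins(series, times)
        np.testing.assert_allclose(vals, centers, atol=2e-3)


class TestOutlierRemoval:
    def test_ceiling_rule_removes_trial_with_extreme_bin(self):
        trials = np.full((5, 29), 100.0)
        trials[2, 7] = 2000.0
        keep, log = spectral.remove_outlier_trials(trials)
        assert not keep[2] and keep.sum() == 4
        assert log[0]["rule"] == "ceiling"

    def test_sd_rule_matches_brute_force_threshold(self):
        rng = np.random.default_rng(3)
        trials = rng.normal(50, 5, size=(20, 29))
        trials[4] += 500.0
        keep, log = spectral.remove_outlier_trials(trials)
        means = trials.mean(axis=1)
        thresh = means.mean() + 3 * means.std()
        expected = means <= thresh
        np.testing.assert_array_equal(keep, expected)

    def test_rule_is_one_sided_above_mean(self):
        trials = np.full((20, 5), 10.0) + np.random.default_rng(4).normal(0, 1, (20, 5))
        trials[3] -= 50.0  # extreme but BELOW the mean
        keep, _ = spectral.remove_outlier_trials(trials)
        assert keep[3]

    def test_homogeneous_trials_all_kept(self):
        keep, log = spectral.remove_outlier_trials(np.full((8, 29), 42.0))
        assert keep.all() and not log

    def test_all_removed_warns(self):
        trials = np.full((2, 3), 5000.0)
        with pytest.warns(UserWarning, match="all trials"):
            keep, _ = spectral.remove_outlier_trials(trials)
        assert not keep.any()


class TestTrialAverage:
    def test_single_trial_identity(self):
        x = np.arange(29.0)[None, :]
        mean, n = spectral.trial_average(x)
        np.testing.assert_array_equal(mean, x[0])
        assert n == 1

    def test_two_trial_mean(self):
        mean, n = spectral.trial_average(np.array([[0.0, 10.0], [10.0, 0.0]]))
        np.testing.assert_array_equal(mean, [5.0, 5.0])

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(5)
        x = rng.random((7, 29))
        keep = np.array([1, 1, 0, 1, 0, 1, 1], dtype=bool)
        mean, n = spectral.trial_average(x, keep)
        np.testing.assert_allclose(mean, x[keep].mean(axis=0))
        assert n == 5


def test_end_to_end_amplitude_invariance():
    """Scaling a raw epoch by any positive constant leaves the percent-change
    bins unchanged."""
    from dmndyn.io import Epoch
    rng = np.random.default_rng(6)
    rate = 500.0
    n = int(20 * rate)
    samples = rng.standard_normal((2, n)) + 2.0
    fam = spectral.build_wavelet_family()
    kwargs = dict(trial_id=1, task="AUT", block=1, stim=0, rate=rate,
                  channel_ids=["a", "b"], t0_offset_s=-2.5,
                  stage_offsets={"stimulus": 0.0}, stage_spans={"stimulus": 15.0})
    e1 = Epoch(samples=samples, **kwargs)
    e2 = Epoch(samples=7.3 * samples, **kwargs)
    b1 = spectral.epoch_band_bins(e1, fam)
    b2 = spectral.epoch_band_bins(e2, fam)
    for key in b1:
        np.testing.assert_allclose(b1[key], b2[key], atol=1e-9)
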