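"""Preprocessing chain: filtering, resampling, baseline, windows, labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from musemo.core import Recording
from musemo.preprocess import (
    band_decompose,
    band_decompose_array,
    bandpass,
    baseline_correct,
    binarize_ratings,
    ica_hook,
    preprocess_dataset,
    resample,
    segment,
)


def sinusoid(freq, fs, seconds, n_channels=1):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return Recording(data=data, fs=fs)


def rms(x):
    return np.sqrt(np.mean(x**2))


def butter_double_pass_gain(freq, low, high, order, fs):
    """Squared magnitude response of the filter applied forward+backward."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs,
                        output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2


class TestBandpass:
    @pytest.mark.parametrize("freq,rel", [(50.0, 0.02), (55.0, 0.10)])
    def test_stopband_attenuation_matches_filter_response(self, freq, rel):
        """Zero-phase filtering attenuates a stopband tone by the squared
        magnitude response of the filter (applied forward+backward); edge
        transients loosen the match as attenuation deepens."""
        rec = sinusoid(freq, 128.0, 10.0)
        out = bandpass(rec, 1.0, 45.0, order=3)
        trimmed = out.data[0, 128:-128]
        ratio = rms(trimmed) / rms(rec.data[0, 128:-128])
        oracle = butter_double_pass_gain(freq, 1.0, 45.0, 3, 128.0)
        assert ratio == pytest.approx(oracle, rel=rel)
        assert ratio < 0.15
        if freq >= 55.0:
            assert ratio < 0.05  # deep stopband

    def test_passband_preserves_rms(self):
        rec = sinusoid(10.0, 128.0, 10.0)
        out = bandpass(rec, 8.0, 13.0, order=3)
        trimmed = out.data[0, 128:-128]
        assert rms(trimmed) == pytest.approx(rms(rec.data[0, 128:-128]), rel=0.05)

    def test_zero_in_zero_out(self):
        rec = Recording(data=np.zeros((2, 256)), fs=128.0)
        out = bandpass(rec, 1.0, 45.0)
        np.testing.assert_allclose(out.data, 0.0)

    def test_band_outside_nyquist_rejected(self):
        rec = sinusoid(10.0, 128.0, 2.0)
        with pytest.raises(ValueError):
            bandpass(rec, 1.0, 70.0)

    def test_passband_filtering_near_idempotent(self):
        rec = sinusoid(10.0, 128.0, 10.0)
        once = bandpass(rec, 8.0, 13.0)
        twice = bandpass(once, 8.0, 13.0)
        r1 = rms(once.data[0, 128:-128])
        r2 = rms(twice.data[0, 128:-128])
        assert abs(r2 - r1) / r1 < 0.10


class TestResample:
    def test_sample_count(self):
        rec = Recording(data=np.random.default_rng(0).standard_normal((2, 20480)),
                        fs=1024.0)
        out = resample(rec, 128.0)
        assert out.data.shape == (2, 2560)
        assert out.fs == 128.0

    def test_sinusoid_preserved(self):
        rec = sinusoid(5.0, 1024.0, 4.0)
        out = resample(rec, 128.0)
        t = np.arange(out.n_samples) / 128.0
        ideal = np.sin(2 * np.pi * 5.0 * t)
        trim = slice(64, -64)
        c = np.corrcoef(out.data[0, trim], ideal[trim])[0, 1]
        assert c > 0.999

    def test_identity_when_rates_equal(self):
        rec = sinusoid(5.0, 128.0, 2.0)
        out = resample(rec, 128.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_upsampling_rejected(self):
        rec = sinusoid(5.0, 128.0, 2.0)
        with pytest.raises(ValueError):
            resample(rec, 256.0)


class TestBaselineCorrect:
    def test_constant_channel_zeroed(self):
        rec = Recording(data=np.full((1, 512), 7.0), fs=128.0)
        out = baseline_correct(rec, 2.0)
        np.testing.assert_allclose(out.data, 0.0)

    def test_baseline_window_dropped(self):
        rec = Recording(
            data=np.random.default_rng(1).standard_normal((3, 20 * 128)),
            fs=128.0)
        out = baseline_correct(rec, 2.0)
        assert out.data.shape == (3, 18 * 128)

    def test_too_short_recording_rejected(self):
        rec = Recording(data=np.zeros((1, 100)), fs=128.0)
        with pytest.raises(ValueError):
            baseline_correct(rec, 2.0)


class TestSegment:
    def test_counts_and_length(self):
        rec = Recording(
            data=np.random.default_rng(0).standard_normal((2, 18 * 128)),
            fs=128.0)
        segs = segment(rec, 2.0, taper="none")
        assert len(segs) == 9
        assert all(s.data.shape == (2, 256) for s in segs)

    def test_full_channel_montage_window_shape(self):
        """A 128-channel recording yields 128 x 256 windows at 128 Hz."""
        rec = Recording(
            data=np.random.default_rng(0).standard_normal((128, 4 * 128)),
            fs=128.0)
        segs = segment(rec, 2.0)
        assert segs[0].data.shape == (128, 256)

    def test_trailing_partial_window_dropped(self):
        rec = Recording(data=np.zeros((1, 300)), fs=128.0)
        segs = segment(rec, 2.0)
        assert len(segs) == 1

    def test_too_short_recording_gives_empty_list(self):
        rec = Recording(data=np.zeros((1, 100)), fs=128.0)
        assert segment(rec, 2.0) == []

    def test_hann_taper_preserves_expected_power(self):
        # Monte-Carlo over 1000 white-noise windows
        rng = np.random.default_rng(5)
        rec = Recording(data=rng.standard_normal((1, 256 * 1000)), fs=128.0)
        plain = segment(rec, 2.0, taper="none")
        tapered = segment(rec, 2.0, taper="hann")
        v_plain = np.mean([s.data.var() for s in plain])
        v_hann = np.mean([s.data.var() for s in tapered])
        assert v_hann / v_plain == pytest.approx(1.0, abs=0.05)

    def test_untapered_segments_reconstruct_recording(self):
        rng = np.random.default_rng(2)
        rec = Recording(data=rng.standard_normal((2, 1000)), fs=128.0)
        segs = segment(rec, 2.0, taper="none")
        rebuilt = np.concatenate([s.data for s in segs], axis=1)
        np.testing.assert_array_equal(rebuilt, rec.data[:, :768])


class TestBandDecompose:
    def test_alpha_sinusoid_lands_in_alpha(self):
        rec = sinusoid(10.0, 128.0, 8.0)
        banded = band_decompose(rec)
        var = {k: v[:, 128:-128].var() for k, v in banded.items()}
        for other in ("theta", "beta", "gamma"):
            assert var["alpha"] > 10 * var[other]

    def test_outputs_match_input_shape(self):
        x = np.random.default_rng(0).standard_normal((3, 512))
        banded = band_decompose_array(x, 128.0)
        assert set(banded) == {"theta", "alpha", "beta", "gamma"}
        assert all(v.shape == x.shape for v in banded.values())

    def test_band_variances_bounded_by_total(self):
        # Parseval-style check on 1-45 Hz broadband noise
        rng = np.random.default_rng(3)
        rec = Recording(data=rng.standard_normal((1, 128 * 16)), fs=128.0)
        rec = bandpass(rec, 1.0, 45.0)
        banded = band_decompose(rec)
        total = rec.data.var()
        assert sum(v.var() for v in banded.values()) <= total * 1.1


class TestBinarize:
    @pytest.mark.parametrize("rating,label", [(3.0, 0), (7.0, 1), (5.0, 1),
                                              (1.0, 0), (9.0, 1), (4.999, 0)])
    def test_threshold_rule(self, rating, label):
        assert binarize_ratings(rating) == label

    def test_out_of_scale_rejected(self):
        for bad in (0.5, 9.5):
            with pytest.raises(ValueError):
                binarize_ratings(bad)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1.0, 9.0), st.floats(1.0, 9.0))
    def test_monotone_in_rating(self, a, b):
        lo, hi = sorted((a, b))
        assert binarize_ratings(lo) <= binarize_ratings(hi)

    def test_vectorized(self):
        np.testing.assert_array_equal(
            binarize_ratings(np.array([2.0, 5.0, 8.0])), [0, 1, 1])


def test_ica_hook_is_identity():
    rec = sinusoid(10.0, 128.0, 2.0)
    assert ica_hook(rec) is rec


def test_end_to_end_segment_count(tiny_dataset):
    """10-s trials at 128 Hz: 2-s baseline dropped, then 4 windows/trial."""
    recordings, ratings = tiny_dataset
    segments = preprocess_dataset(recordings, ratings)
    usable = 10.0 - 2.0
    assert len(segments) == len(recordings) * int(usable // 2.0)
    seg = segments[0]
    assert seg.fs == 128.0
    assert seg.data.shape == (8, 256)
    assert seg.valence_label in (0, 1)


def test_labels_follow_class_semantics(tiny_dataset):
    recordings, ratings = tiny_dataset
    segments = preprocess_dataset(recordings, ratings)
    by_class = {}
    for s in segments:
        by_class.setdefault(s.class_name, set()).add(
            (s.valence_label, s.arousal_label))
    # fear: low valence/high arousal; happy: high/high; calm: high/low; sad: low/low
    assert by_class["fear"] == {(0, 1)}
    assert by_class["happy"] == {(1, 1)}
    assert by_class["calm"] == {(1, 0)}
    assert by_class["sad"] == {(0, 0)}
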