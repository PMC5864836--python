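import numpy as np
import pytest

from eggkit import (
    BipolarSignal,
    Event,
    EventLog,
    MultichannelRecording,
    align_by_event,
    best_pair,
    compute_spectrogram,
    egg_features,
    find_isolated_meals,
    percent_normal,
    snr,
)

FS = 5.0


def sinusoid(freq_hz, amp=100.0, duration_s=7200.0, fs=FS, phase=0.3):
    t = np.arange(int(duration_s * fs)) / fs
    return BipolarSignal(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs)


def white_noise(rms, duration_s, fs=FS, seed=7):
    rng = np.random.default_rng(seed)
    return BipolarSignal(rng.normal(0, rms, int(duration_s * fs)), fs)


class TestSpectrogramFraming:
    def test_window_count_two_hours(self):
        spec = compute_spectrogram(sinusoid(0.05, duration_s=7200))
        assert spec.n_windows == (36000 - 1200) // 300 + 1 == 117

    def test_frequency_resolution_law(self):
        spec = compute_spectrogram(sinusoid(0.05))
        np.testing.assert_allclose(np.diff(spec.freqs), 1 / 240, rtol=1e-12)

    def test_time_spacing_law(self):
        spec = compute_spectrogram(sinusoid(0.05), overlap_frac=0.75)
        np.testing.assert_allclose(np.diff(spec.times), 240 * 0.25)

    def test_sinusoid_peak_bin(self):
        spec = compute_spectrogram(sinusoid(0.05))
        peak = spec.freqs[np.argmax(spec.power_db, axis=1)]
        assert np.all(np.abs(peak - 0.05) <= 1 / 240 + 1e-12)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(sinusoid(0.05, duration_s=100))

    def test_white_noise_flat_within_3db(self):
        spec = compute_spectrogram(white_noise(50, duration_s=4 * 3600))
        assert spec.n_windows >= 50
        mean_db = spec.power_db.mean(axis=0)
        inband = mean_db[(spec.freqs >= 0.02) & (spec.freqs <= 0.20)]
        assert inband.max() - inband.min() < 3.0

    def test_parseval_sanity_on_noise(self):
        sig = white_noise(30, duration_s=3600)
        spec = compute_spectrogram(sig)
        df = spec.freqs[1] - spec.freqs[0]
        total = (10 ** (spec.power_db / 10)).sum(axis=1).mean() * df
        # compare with the mean tapered, mean-removed segment power,
        # corrected for the taper's incoherent gain (PSD normalization)
        W, hop = 1200, 300
        from scipy.signal import get_window

        w = get_window("hamming", W)
        seg_power = []
        for i in range(spec.n_windows):
            seg = sig.samples[i * hop : i * hop + W]
            seg = (seg - seg.mean()) * w
            seg_power.append((seg**2).sum() / (w**2).sum())
        assert total == pytest.approx(np.mean(seg_power), rel=0.01)


class TestSnr:
    def test_strong_slow_wave_high_snr(self):
        rng = np.random.default_rng(1)
        sig = sinusoid(0.05, amp=100)
        noisy = BipolarSignal(sig.samples + rng.normal(0, 5, len(sig)), FS)
        assert snr(compute_spectrogram(noisy)) > 10.0

    def test_white_noise_snr_near_zero(self):
        spec = compute_spectrogram(white_noise(40, duration_s=8 * 3600))
        assert spec.n_windows >= 100
        assert abs(snr(spec)) < 1.0

    def test_out_of_band_tone_negative_snr(self):
        assert snr(compute_spectrogram(sinusoid(0.10))) < 0.0

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(5)
        x = sinusoid(0.05, amp=100).samples + rng.normal(0, 20, 36000)
        s1 = snr(compute_spectrogram(BipolarSignal(x, FS)))
        s2 = snr(compute_spectrogram(BipolarSignal(100 * x, FS)))
        assert s1 == pytest.approx(s2, abs=1e-9)


class TestPercentNormal:
    def test_pure_3cpm_fully_normal(self):
        assert percent_normal(compute_spectrogram(sinusoid(0.05))) == 100.0

    def test_pure_5cpm_fully_abnormal(self):
        assert percent_normal(compute_spectrogram(sinusoid(5 / 60))) == 0.0

    def test_mixed_record_fraction(self):
        # 3 h at 3 cpm then 1 h at 6 cpm: 75% of windows normal, give or
        # take the windows straddling the transition
        t3 = np.arange(int(3 * 3600 * FS)) / FS
        t1 = np.arange(int(1 * 3600 * FS)) / FS
        x = np.concatenate(
            [100 * np.sin(2 * np.pi * 0.05 * t3), 100 * np.sin(2 * np.pi * 0.1 * t1)]
        )
        spec = compute_spectrogram(BipolarSignal(x, FS))
        expected = 75.0
        one_window = 100.0 / spec.n_windows
        assert abs(percent_normal(spec) - expected) <= 4 * one_window

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        x = 100 * np.sin(2 * np.pi * 0.05 * np.arange(36000) / FS)
        x = x + rng.normal(0, 40, x.size)
        p1 = percent_normal(compute_spectrogram(BipolarSignal(x, FS)))
        p2 = percent_normal(compute_spectrogram(BipolarSignal(900 * x, FS)))
        assert p1 == p2
        assert 0 <= p1 <= 100


class TestEggFeatures:
    def test_amplitude_doubling_raises_band_power_6db(self):
        # off bin center: leakage keeps all band bins above the log floor
        f1 = egg_features(compute_spectrogram(sinusoid(0.0497, amp=100)))
        f2 = egg_features(compute_spectrogram(sinusoid(0.0497, amp=200)))
        shift = f2.band_power_db - f1.band_power_db
        np.testing.assert_allclose(shift, 20 * np.log10(2), atol=0.01)

    def test_white_noise_normalized_power_near_zero(self):
        spec = compute_spectrogram(white_noise(40, duration_s=8 * 3600))
        feats = egg_features(spec)
        assert feats.times.size >= 100
        assert abs(feats.normalized_power_db.mean()) < 1.0

    def test_dominant_frequency_sweep(self):
        for f in np.linspace(0.025, 0.19, 12):
            feats = egg_features(compute_spectrogram(sinusoid(f, duration_s=3600)))
            assert np.all(np.abs(feats.dominant_freq_hz - f) <= 1 / 240 + 1e-12)

    def test_is_normal_consistent_with_percent_normal(self):
        spec = compute_spectrogram(sinusoid(0.05))
        feats = egg_features(spec)
        assert 100.0 * feats.is_normal.mean() == percent_normal(spec)

    def test_dominant_frequency_within_analysis_band(self):
        spec = compute_spectrogram(white_noise(40, 7200))
        feats = egg_features(spec)
        assert np.all(feats.dominant_freq_hz >= 0.02 - 1e-12)
        assert np.all(feats.dominant_freq_hz <= 0.20 + 1e-12)


class TestBestPair:
    def test_pair_containing_source_selected(self):
        rng = np.random.default_rng(11)
        n = 36000
        t = np.arange(n) / FS
        s = 100 * np.sin(2 * np.pi * 0.05 * t)
        rec = MultichannelRecording(
            np.vstack(
                [
                    s + rng.normal(0, 20, n),
                    rng.normal(0, 20, n),
                    rng.normal(0, 20, n),
                ]
            ),
            FS,
            ["A", "B", "C"],
        )
        meas, ref, value = best_pair(rec)
        assert "A" in (meas, ref)
        assert value > 5.0

    def test_two_channels_single_candidate(self, small_recording):
        rec = MultichannelRecording(
            small_recording.samples[:2], FS, ["A", "B"]
        )
        meas, ref, _ = best_pair(rec)
        assert (meas, ref) == ("A", "B")

    def test_identical_channels_warn_and_first_pair(self):
        x = np.tile(np.sin(np.arange(3000)), (3, 1))
        rec = MultichannelRecording(x, FS, ["A", "B", "C"])
        with pytest.warns(UserWarning, match="identical"):
            meas, ref, value = best_pair(rec)
        assert (meas, ref) == ("A", "B")
        assert value == 0.0


class TestEventAlignment:
    @staticmethod
    def _features(duration_s=10 * 3600, value_fn=None):
        sig = sinusoid(0.05, duration_s=duration_s)
        feats = egg_features(compute_spectrogram(sig))
        if value_fn is not None:
            feats.normalized_power_db = value_fn(feats.times)
        return feats

    def test_single_event_identity(self):
        feats = self._features(value_fn=lambda t: t / 100.0)
        log = EventLog([Event(5000.0, "meal")])
        al = align_by_event(feats, log, "meal", pre_s=0.0, post_s=0.0)
        assert al.rows.shape[0] == 1
        assert al.mean[np.argmin(np.abs(al.rel_times))] == pytest.approx(50.0, rel=1e-6)

    def test_duplicate_anchors_zero_std(self):
        feats = self._features()
        log = EventLog([Event(4000.0, "meal"), Event(4000.0, "meal")])
        al = align_by_event(feats, log, "meal", 600.0, 600.0)
        np.testing.assert_allclose(al.std, 0.0, atol=1e-12)

    def test_uncovered_event_dropped_with_warning(self):
        feats = self._features()
        log = EventLog([Event(100.0, "meal"), Event(5 * 3600.0, "meal")])
        with pytest.warns(UserWarning, match="dropped"):
            al = align_by_event(feats, log, "meal", 3600.0, 3600.0)
        assert al.rows.shape[0] == 1
        assert al.anchors[0].time_s == 5 * 3600.0

    def test_all_uncovered_raises(self):
        feats = self._features()
        log = EventLog([Event(10.0, "meal")])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="covered"):
                align_by_event(feats, log, "meal", 3600.0, 3600.0)


class TestIsolatedMeals:
    def test_lone_meal_is_isolated(self):
        log = EventLog([Event(6 * 3600.0, "meal")])
        assert len(find_isolated_meals(log)) == 1

    def test_snack_one_hour_later_disqualifies(self):
        log = EventLog([Event(6 * 3600.0, "meal"), Event(7 * 3600.0, "snack")])
        assert find_isolated_meals(log) == []

    def test_meals_six_hours_apart_both_isolated(self):
        log = EventLog([Event(0.0, "meal"), Event(6 * 3600.0, "meal")])
        assert len(find_isolated_meals(log)) == 2

    def test_meals_four_hours_apart_neither_isolated(self):
        log = EventLog([Event(0.0, "meal"), Event(4 * 3600.0, "meal")])
        assert find_isolated_meals(log) == []

    def test_fasting_window_enforced(self):
        log = EventLog(
            [Event(2 * 3600.0, "bowel_movement"), Event(5 * 3600.0, "meal")]
        )
        assert find_isolated_meals(log) == []
        assert len(find_isolated_meals(log, fast_before_s=2 * 3600.0)) == 1
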