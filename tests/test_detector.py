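import numpy as np
import pytest

from wheezekit.detector import (DetectorConfig, detect_wheezes,
                                evaluate_detector, frame_peaks, link_tracks)
from wheezekit.melspec import MelSpectrogram, mel_spectrogram

from _oracles import oracle_events, random_grid


def grid_melspec(db, band_spacing_hz=40.0, hop=512, window=1024, sr=20000.0):
    db = np.asarray(db, dtype=float)
    centers = 100.0 + band_spacing_hz * np.arange(db.shape[0])
    times = (hop * np.arange(db.shape[1]) + window / 2) / sr
    return MelSpectrogram(power_db=db, frame_times=times,
                          band_center_freqs=centers,
                          params={"window_samples": window, "hop_samples": hop,
                                  "n_bands": db.shape[0], "fmin": centers[0],
                                  "fmax": centers[-1], "sample_rate": sr,
                                  "channel": "contact"})


def ridge_grid(band, n_frames=20, n_bands=8, level=0.0):
    db = np.full((n_bands, n_frames), -80.0)
    db[band, :] = level
    return db


class TestFramePeaks:
    def test_single_tone_single_peak(self):
        t = np.arange(int(5 * 20000)) / 20000
        x = np.sin(2 * np.pi * 400 * t) + 1e-4 * np.random.default_rng(0) \
            .standard_normal(t.size)
        ms = mel_spectrogram(x, 20000.0, "contact")
        peaks = frame_peaks(ms)
        spacing = np.max(np.diff(ms.band_center_freqs))
        assert all(len(p) == 1 for p in peaks)
        assert all(abs(p[0][0] - 400.0) <= spacing for p in peaks)

    def test_silence_has_no_peaks(self):
        ms = grid_melspec(np.full((8, 12), -80.0))
        assert all(len(p) == 0 for p in frame_peaks(ms))

    def test_white_noise_rarely_peaks_and_never_forms_events(self):
        """Isolated noise peaks are common enough (single-bin mel bands are
        chi-square distributed) that specificity must come from the linking
        and duration rules: frame-level peaks stay rare, and no noise
        segment ever yields a wheeze event."""
        from wheezekit.detector import detect_wheezes
        fp_frames, total, flags = 0, 0, 0
        cfg = DetectorConfig(baseline_margin_db=10.0)
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(int(5 * 20000))
            ms = mel_spectrogram(x, 20000.0, "contact")
            peaks = frame_peaks(ms, cfg)
            fp_frames += sum(1 for p in peaks if p)
            total += len(peaks)
            flags += detect_wheezes(ms, cfg)[1]
        assert fp_frames / total <= 0.12
        assert flags == 0


class TestLinking:
    def test_constant_ridge_links_fully(self):
        ms = grid_melspec(ridge_grid(band=3))
        peaks = frame_peaks(ms)
        tracks = link_tracks(peaks)
        assert len(tracks) == 1 and len(tracks[0]) == 20

    def test_alternating_ridge_never_links(self):
        db = np.full((8, 12), -80.0)
        for j in range(12):
            db[2 if j % 2 == 0 else 7, j] = 0.0   # 200 Hz jumps at 40 Hz/band
        tracks = link_tracks(frame_peaks(grid_melspec(db)))
        assert max(len(t) for t in tracks) == 1

    def test_parallel_ridges_stay_disjoint(self):
        db = np.full((12, 15), -80.0)
        db[2, :] = 0.0
        db[10, :] = 0.0   # 8 bands * 40 Hz = 320 Hz apart
        tracks = link_tracks(frame_peaks(grid_melspec(db)))
        assert len(tracks) == 2
        assert all(len(t) == 15 for t in tracks)


class TestDetectRules:
    def test_oracle_equivalence_on_random_grids(self):
        rng = np.random.default_rng(99)
        cfg = DetectorConfig()
        for _ in range(200):
            ms = random_grid(rng)
            events, _ = detect_wheezes(ms, cfg)
            got = sorted((e.onset, e.offset,
                          tuple(round(f, 6) for _, f in e.freq_track))
                         for e in events)
            assert got == oracle_events(ms)

    def test_margin_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            ms = random_grid(rng)
            counts = [len(detect_wheezes(ms, DetectorConfig(
                baseline_margin_db=m))[0]) for m in (4.0, 8.0, 16.0)]
            assert counts[0] >= counts[1] >= counts[2]

    def test_duration_monotonicity(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            ms = random_grid(rng)
            counts = [len(detect_wheezes(ms, DetectorConfig(
                min_duration_s=d))[0]) for d in (0.05, 0.1, 0.3)]
            assert counts[0] >= counts[1] >= counts[2]

    def test_short_ridge_rejected_long_ridge_kept(self):
        # 4 frames at hop 25.6 ms span 76.8 ms: below the >100 ms rule
        short = ridge_grid(band=3, n_frames=12)
        short[3, :] = -80.0
        short[3, 2:6] = 0.0
        events, flag = detect_wheezes(grid_melspec(short))
        assert events == [] and flag is False

        long = ridge_grid(band=3, n_frames=12)   # 11 hops = 281.6 ms
        events, flag = detect_wheezes(grid_melspec(long))
        assert len(events) == 1 and flag is True

    def test_min_freq_rule_toggle(self):
        db = np.full((8, 12), -80.0)
        db[1, :] = 0.0   # 140 Hz with default spacing; move centers below 100
        ms = grid_melspec(db)
        ms.band_center_freqs = ms.band_center_freqs - 60.0   # band 1 -> 80 Hz
        events_on, _ = detect_wheezes(ms, DetectorConfig(enforce_min_freq=True))
        events_off, _ = detect_wheezes(ms, DetectorConfig(enforce_min_freq=False))
        assert events_on == []
        assert len(events_off) == 1

    def test_determinism(self):
        rng = np.random.default_rng(17)
        ms = random_grid(rng)
        a, _ = detect_wheezes(ms)
        b, _ = detect_wheezes(ms)
        assert [(e.onset, e.offset, e.freq_track) for e in a] == \
               [(e.onset, e.offset, e.freq_track) for e in b]


class TestEvaluateDetector:
    def test_confusion_arithmetic(self):
        flags = [True] * 45 + [False] * 5 + [False] * 40 + [True] * 10
        labels = [True] * 50 + [False] * 50
        m = evaluate_detector(flags, labels)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.80)

    def test_perfect_predictions(self):
        m = evaluate_detector([True, False, True], [True, False, True])
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1, 1, 1)

    def test_single_class_labels_flagged(self):
        with pytest.warns(UserWarning, match="specificity"):
            m = evaluate_detector([True, True], [True, True])
        assert np.isnan(m["specificity"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detector([], [])
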