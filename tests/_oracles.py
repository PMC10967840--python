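"""Independent brute-force reference for the time-frequency rules.

Written deliberately in the most naive style (explicit loops, statistics
module, no shared code with the package) so it can serve as an oracle for
the vectorized detector on small spectrogram grids.
"""

from __future__ import annotations

import statistics

import numpy as np

from wheezekit.melspec import MelSpectrogram


def oracle_events(melspec, margin_db=8.0, tol_hz=50.0, min_dur_s=0.100,
                  min_freq_hz=100.0, enforce_min_freq=True, max_gap=0):
    """All (onset, offset, freq tuple) events satisfying the rules."""
    db = melspec.power_db
    centers = list(melspec.band_center_freqs)
    n_bands, n_frames = db.shape

    # naive per-frame peak picking: interior maxima that strictly dominate
    # immediate neighbours, are no smaller than second neighbours, and
    # exceed the frame median by the margin
    peaks = []
    for j in range(n_frames):
        col = [float(db[b, j]) for b in range(n_bands)]
        baseline = statistics.median(col)
        frame = []
        for b in range(1, n_bands - 1):
            if not (col[b] > col[b - 1] and col[b] > col[b + 1]):
                continue
            if b >= 2 and col[b] < col[b - 2]:
                continue
            if b <= n_bands - 3 and col[b] < col[b + 2]:
                continue
            if col[b] > baseline + margin_db:
                frame.append(centers[b])
        peaks.append(sorted(frame))

    # naive greedy linking, tracks extended in creation order
    tracks, active = [], []
    for j in range(n_frames):
        available = list(peaks[j])
        for track in active:
            head = track["freqs"][-1]
            best = None
            for f in available:
                if abs(f - head) <= tol_hz:
                    if best is None or (abs(f - head), f) < (abs(best - head),
                                                             best):
                        best = f
            if best is not None:
                track["frames"].append(j)
                track["freqs"].append(best)
                track["gap"] = 0
                available.remove(best)
            else:
                track["gap"] += 1
        keep = []
        for track in active:
            if track["gap"] > max_gap:
                tracks.append(track)
            else:
                keep.append(track)
        active = keep
        for f in available:
            active.append({"frames": [j], "freqs": [f], "gap": 0})
    tracks.extend(active)

    hop_s = melspec.hop_s
    times = melspec.frame_times
    events = []
    for track in tracks:
        duration = (track["frames"][-1] - track["frames"][0]) * hop_s
        if duration <= min_dur_s:
            continue
        mean_freq = sum(track["freqs"]) / len(track["freqs"])
        if enforce_min_freq and mean_freq < min_freq_hz:
            continue
        events.append((float(times[track["frames"][0]]),
                       float(times[track["frames"][-1]]),
                       tuple(round(f, 6) for f in track["freqs"])))
    return sorted(events)


def random_grid(rng, n_bands=8, n_frames=12, band_spacing_hz=40.0,
                sample_rate=20000.0, hop=512, window=1024):
    """A small synthetic dB grid with ridge fragments and isolated peaks."""
    centers = 100.0 + band_spacing_hz * np.arange(n_bands)
    db = np.full((n_bands, n_frames), -80.0)
    for _ in range(rng.integers(0, 4)):
        band = int(rng.integers(0, n_bands))
        start = int(rng.integers(0, n_frames))
        length = int(rng.integers(1, n_frames - start + 1))
        level = rng.uniform(-30.0, 0.0)
        for j in range(start, start + length):
            if rng.random() < 0.3:
                band = int(np.clip(band + rng.integers(-2, 3), 0, n_bands - 1))
            db[band, j] = max(db[band, j], level + rng.uniform(-2, 2))
    for _ in range(rng.integers(0, 6)):
        db[rng.integers(0, n_bands), rng.integers(0, n_frames)] = \
            rng.uniform(-40.0, 0.0)
    times = (hop * np.arange(n_frames) + window / 2) / sample_rate
    params = {"window_samples": window, "hop_samples": hop,
              "n_bands": n_bands, "fmin": centers[0], "fmax": centers[-1],
              "sample_rate": sample_rate, "channel": "contact"}
    return MelSpectrogram(power_db=db, frame_times=times,
                          band_center_freqs=centers, params=params)
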