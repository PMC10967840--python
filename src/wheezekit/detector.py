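"""Deterministic time-frequency wheeze detector.

A wheeze appears in a mel spectrogram as a sustained narrowband ridge.  The
detector works in three steps on the dB matrix:

1. **frame peaks** — per frame (column), local maxima along the band axis
   whose power exceeds the frame baseline (median dB across bands) by a
   margin (default 8 dB);
2. **track linking** — greedy frame-to-frame linking: a peak extends a track
   only if its frequency is within 50 Hz of the track head (a wheeze is a
   near-constant tone); ties resolved by smaller |df|, then lower frequency;
3. **duration rule** — only tracks strictly longer than 100 ms (and, when
   enabled, with mean frequency >= 100 Hz) become wheeze events.

Track duration is (n_frames - 1) * hop and event onset/offset are frame
centers, so a 77 ms tone can never satisfy the >100 ms rule while a genuine
ridge's timing is recovered to within one hop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .melspec import MelSpectrogram


@dataclass
class DetectorConfig:
    """Thresholds of the time-frequency rules (all strictly positive)."""

    baseline_margin_db: float = 8.0
    link_tolerance_hz: float = 50.0
    min_duration_s: float = 0.100
    min_freq_hz: float = 100.0
    enforce_min_freq: bool = True
    max_gap_frames: int = 0
    baseline_statistic: str = "median"   # or "mean"

    def __post_init__(self) -> None:
        for name in ("baseline_margin_db", "link_tolerance_hz",
                     "min_duration_s", "min_freq_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class WheezeEvent:
    """A detected wheeze: a linked ridge longer than the duration rule."""

    onset: float
    offset: float
    freq_track: list[tuple[float, float]] = field(default_factory=list)

    @property
    def mean_freq(self) -> float:
        return float(np.mean([f for _, f in self.freq_track]))

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def frame_peaks(melspec: MelSpectrogram, config: DetectorConfig | None = None
                ) -> list[list[tuple[float, float]]]:
    """Per-frame (frequency Hz, power dB) peaks above the baseline margin.

    A peak is a band strictly greater than its immediate neighbours and no
    smaller than its second neighbours (the 64 mel bands oversample the STFT
    resolution by about 2x at the low end, so a single tone can otherwise
    split into twin maxima), whose power exceeds the frame's baseline
    statistic by ``baseline_margin_db``.  Frequencies are reported at band
    centers.
    """
    config = config or DetectorConfig()
    db = melspec.power_db
    centers = melspec.band_center_freqs
    n_bands = db.shape[0]
    stat = np.median if config.baseline_statistic == "median" else np.mean
    peaks_per_frame: list[list[tuple[float, float]]] = []
    for j in range(db.shape[1]):
        col = db[:, j]
        baseline = stat(col)
        frame = []
        for b in range(1, n_bands - 1):
            if not (col[b] > col[b - 1] and col[b] > col[b + 1]):
                continue
            if b >= 2 and col[b] < col[b - 2]:
                continue
            if b <= n_bands - 3 and col[b] < col[b + 2]:
                continue
            if col[b] > baseline + config.baseline_margin_db:
                frame.append((float(centers[b]), float(col[b])))
        peaks_per_frame.append(frame)
    return peaks_per_frame


def link_tracks(peaks_per_frame: list[list[tuple[float, float]]],
                config: DetectorConfig | None = None
                ) -> list[list[tuple[int, float]]]:
    """Greedy nearest-frequency linking of per-frame peaks into ridge tracks.

    Returns tracks as lists of (frame_index, frequency Hz).  Active tracks
    are extended in order of creation; each candidate peak joins at most one
    track; the closest-in-frequency peak wins, ties broken toward the lower
    frequency.  A track may bridge up to ``max_gap_frames`` empty frames.
    """
    config = config or DetectorConfig()
    finished: list[list[tuple[int, float]]] = []
    active: list[dict] = []   # {"points": [(frame, freq)], "gap": int}

    for j, frame in enumerate(peaks_per_frame):
        freqs = sorted(f for f, _ in frame)
        unclaimed = list(freqs)
        for track in active:
            head = track["points"][-1][1]
            candidates = [f for f in unclaimed
                          if abs(f - head) <= config.link_tolerance_hz]
            if candidates:
                best = min(candidates, key=lambda f: (abs(f - head), f))
                track["points"].append((j, best))
                track["gap"] = 0
                unclaimed.remove(best)
            else:
                track["gap"] += 1
        still_active = []
        for track in active:
            if track["gap"] > config.max_gap_frames:
                finished.append(track["points"])
            else:
                still_active.append(track)
        active = still_active
        for f in unclaimed:
            active.append({"points": [(j, f)], "gap": 0})

    finished.extend(track["points"] for track in active)
    finished.sort(key=lambda pts: (pts[0][0], pts[0][1]))
    return finished


def detect_wheezes(melspec: MelSpectrogram, config: DetectorConfig | None = None
                   ) -> tuple[list[WheezeEvent], bool]:
    """Run the full time-frequency rule set on one mel spectrogram.

    Returns (events, segment_flag) where the flag is True iff at least one
    event satisfies all rules.
    """
    config = config or DetectorConfig()
    peaks = frame_peaks(melspec, config)
    tracks = link_tracks(peaks, config)
    hop_s = melspec.hop_s
    times = melspec.frame_times

    events: list[WheezeEvent] = []
    for points in tracks:
        duration = (points[-1][0] - points[0][0]) * hop_s
        if duration <= config.min_duration_s:
            continue
        mean_freq = float(np.mean([f for _, f in points]))
        if config.enforce_min_freq and mean_freq < config.min_freq_hz:
            continue
        events.append(WheezeEvent(
            onset=float(times[points[0][0]]),
            offset=float(times[points[-1][0]]),
            freq_track=[(float(times[j]), f) for j, f in points]))
    return events, bool(events)


def evaluate_detector(segment_flags, labels) -> dict[str, float]:
    """Accuracy / sensitivity / specificity of boolean flags vs boolean labels.

    An undefined ratio (no positives or no negatives in the labels) is
    reported as NaN with a warning.
    """
    flags = np.asarray(segment_flags, dtype=bool)
    truth = np.asarray(labels, dtype=bool)
    if flags.size == 0 or flags.size != truth.size:
        raise ValueError("flags and labels must be equal-length and non-empty")
    tp = int(np.sum(flags & truth))
    tn = int(np.sum(~flags & ~truth))
    fp = int(np.sum(flags & ~truth))
    fn = int(np.sum(~flags & truth))

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return {
        "accuracy": (tp + tn) / flags.size,
        "sensitivity": _ratio(tp, tp + fn, "sensitivity"),
        "specificity": _ratio(tn, tn + fp, "specificity"),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }
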