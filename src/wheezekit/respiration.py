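"""Respiration phase and rate from the contact channel's low-frequency content.

A DC-coupled chest-wall accelerometer sees breathing directly as a sub-1 Hz
displacement ramp.  With the subject upright and breathing deeply, rising
ramps are inspiration and falling ramps expiration; this module documents
that assumption rather than compensating for posture.

Chain: 5 Hz order-10 zero-phase low-pass -> centered moving average
(default 0.5 s) -> mean centering.  Phase intervals are delimited by local
extrema of the smoothed motion (with a prominence floor of 10% of the motion
range to ignore micro-ripples); the respiration rate is 60 over the median
duration of complete inspiration+expiration cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .audio_io import Recording
from .detector import WheezeEvent

logger = logging.getLogger(__name__)


@dataclass
class RespirationTrace:
    motion: np.ndarray
    sample_rate: float
    phase_intervals: list[tuple[float, float, str]] = field(default_factory=list)
    rate: float | None = None


def extract_motion(recording: Recording, cutoff_hz: float = 5.0,
                   order: int = 10, smooth_window_s: float = 0.5) -> np.ndarray:
    """Low-pass -> moving average -> mean centering; length preserved."""
    nyquist = recording.sample_rate / 2
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist}")
    sos = signal.butter(order, cutoff_hz / nyquist, btype="lowpass", output="sos")
    x = signal.sosfiltfilt(sos, np.asarray(recording.samples, dtype=np.float64))
    win = max(1, int(round(smooth_window_s * recording.sample_rate)))
    if win > 1:
        kernel = np.ones(win) / win
        pad = win // 2
        padded = np.pad(x, pad, mode="edge")
        x = np.convolve(padded, kernel, mode="same")[pad:pad + x.size]
    return x - x.mean()


def phase_segments(motion: np.ndarray, sample_rate: float,
                   prominence_fraction: float = 0.1
                   ) -> list[tuple[float, float, str]]:
    """Alternating inspiration/expiration intervals from motion extrema.

    Rising portions (trough -> peak) are inspiration.  The leading and
    trailing partial ramps are labeled by their slope so the intervals tile
    the whole trace.  Without any usable extremum a single "unknown"
    interval is returned with a warning.
    """
    motion = np.asarray(motion, dtype=np.float64)
    duration = motion.size / sample_rate
    span = motion.max() - motion.min()
    if span <= 0:
        logger.warning("flat motion trace; phase unknown")
        return [(0.0, duration, "unknown")]
    prominence = prominence_fraction * span
    peaks, _ = signal.find_peaks(motion, prominence=prominence)
    troughs, _ = signal.find_peaks(-motion, prominence=prominence)
    extrema = sorted([(int(i), "peak") for i in peaks]
                     + [(int(i), "trough") for i in troughs])
    if not extrema:
        logger.warning("no extrema found; phase unknown")
        return [(0.0, duration, "unknown")]

    intervals: list[tuple[float, float, str]] = []
    # leading partial ramp: ends at the first extremum
    first_idx, first_kind = extrema[0]
    if first_idx > 0:
        intervals.append((0.0, first_idx / sample_rate,
                          "inspiration" if first_kind == "peak" else "expiration"))
    for (i0, k0), (i1, k1) in zip(extrema[:-1], extrema[1:]):
        if k0 == k1:
            continue  # duplicate extremum kind; skip degenerate interval
        label = "inspiration" if k1 == "peak" else "expiration"
        intervals.append((i0 / sample_rate, i1 / sample_rate, label))
    last_idx, last_kind = extrema[-1]
    if last_idx < motion.size - 1:
        intervals.append((last_idx / sample_rate, duration,
                          "expiration" if last_kind == "peak" else "inspiration"))
    return intervals


def respiration_rate(phase_intervals: list[tuple[float, float, str]]) -> float:
    """Breaths/min = 60 / median duration of inspiration+expiration cycles."""
    cycles = []
    for (a0, a1, lab0), (b0, b1, lab1) in zip(phase_intervals[:-1],
                                              phase_intervals[1:]):
        if lab0 == "inspiration" and lab1 == "expiration" and abs(a1 - b0) < 1e-9:
            cycles.append((b1 - a0))
    if len(cycles) < 2:
        raise ValueError("need at least two complete breath cycles to estimate a rate")
    return 60.0 / float(np.median(cycles))


def analyze_respiration(recording: Recording, cutoff_hz: float = 5.0,
                        order: int = 10, smooth_window_s: float = 0.5,
                        prominence_fraction: float = 0.1) -> RespirationTrace:
    """Motion, phase intervals and (when possible) rate for one recording."""
    motion = extract_motion(recording, cutoff_hz, order, smooth_window_s)
    intervals = phase_segments(motion, recording.sample_rate, prominence_fraction)
    try:
        rate = respiration_rate(intervals)
    except ValueError:
        rate = None
    return RespirationTrace(motion=motion, sample_rate=recording.sample_rate,
                            phase_intervals=intervals, rate=rate)


def tag_events_with_phase(events: list[WheezeEvent],
                          phase_intervals: list[tuple[float, float, str]]
                          ) -> list[str]:
    """Label each event by the phase holding the majority of its duration."""
    labels = []
    for event in events:
        overlaps: dict[str, float] = {}
        for onset, offset, lab in phase_intervals:
            o = max(0.0, min(event.offset, offset) - max(event.onset, onset))
            if o > 0:
                overlaps[lab] = overlaps.get(lab, 0.0) + o
        labels.append(max(overlaps, key=overlaps.get) if overlaps else "unknown")
    return labels
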