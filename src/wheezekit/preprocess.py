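"""Contact-channel denoising chain and 5-second segmentation.

The chain is bandpass (60-2000 Hz, order-10 Butterworth prototype applied
zero-phase) -> Savitzky-Golay smoothing (window 9) -> db3 discrete-wavelet
soft-threshold denoising -> non-overlapping 5 s segments, each rescaled to
[-1, 1] by its own max absolute value.  The air channel skips the SG/wavelet
stages and receives only an optional generic bandpass.

All stages are linear up to the wavelet threshold, and each segment is
normalized independently, so the pipeline output is invariant to overall
input gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .audio_io import Recording

logger = logging.getLogger(__name__)

SEGMENT_SECONDS = 5.0


@dataclass
class Segment:
    """A 5-second analysis excerpt scaled to [-1, 1]."""

    samples: np.ndarray
    sample_rate: float
    start_time: float
    recording_id: str = ""
    segment_index: int = 0
    label: str = "unlabeled"

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def bandpass(samples: np.ndarray, sample_rate: float, low_hz: float = 60.0,
             high_hz: float = 2000.0, order: int = 10) -> np.ndarray:
    """Zero-phase Butterworth bandpass (prototype order ``order``).

    Applied forward-backward (``sosfiltfilt``) so event timing used by the
    detector and the respiration alignment is not skewed by group delay.
    """
    nyquist = sample_rate / 2
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"bandpass corners ({low_hz}, {high_hz}) must satisfy "
            f"0 < low < high < Nyquist ({nyquist})")
    sos = signal.butter(order, [low_hz / nyquist, high_hz / nyquist],
                        btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=np.float64))


def sgolay_smooth(samples: np.ndarray, window: int = 9, polyorder: int = 3
                  ) -> np.ndarray:
    """Savitzky-Golay smoothing; exactly reproduces polynomials of the fitted degree."""
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    return signal.savgol_filter(np.asarray(samples, dtype=np.float64),
                                window, polyorder)


def wavelet_denoise(samples: np.ndarray, wavelet: str = "db3", level: int = 4,
                    threshold_rule: str | float = "universal") -> np.ndarray:
    """Soft-threshold wavelet denoising.

    ``threshold_rule`` is ``"universal"`` (sigma * sqrt(2 ln N), sigma from
    the MAD of the finest detail band) or an explicit numeric threshold;
    0 leaves the transform-inverse round trip exact to floating precision.
    """
    samples = np.asarray(samples, dtype=np.float64)
    max_level = pywt.dwt_max_level(samples.size, pywt.Wavelet(wavelet).dec_len)
    if level < 1 or level > max_level:
        raise ValueError(f"level must be in 1..{max_level} for length {samples.size}")
    coeffs = pywt.wavedec(samples, wavelet, level=level)
    if threshold_rule == "universal":
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
        threshold = sigma * np.sqrt(2 * np.log(max(samples.size, 2)))
    else:
        threshold = float(threshold_rule)
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
    if threshold > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, threshold, mode="soft")
                                for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet)
    return out[:samples.size]


def segment_and_scale(samples: np.ndarray, sample_rate: float,
                      segment_s: float = SEGMENT_SECONDS,
                      recording_id: str = "") -> list[Segment]:
    """Cut into consecutive non-overlapping segments, each scaled to max |x| = 1.

    The trailing remainder shorter than one segment is dropped (count logged).
    All-zero segments are left at zero rather than divided by zero.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    samples = np.asarray(samples, dtype=np.float64)
    seg_len = int(round(segment_s * sample_rate))
    n_segments = samples.size // seg_len
    if n_segments == 0:
        logger.warning("recording shorter than one %.1f s segment; nothing kept",
                       segment_s)
        return []
    dropped = samples.size - n_segments * seg_len
    if dropped:
        logger.info("dropping trailing %d samples (%.2f s) shorter than a segment",
                    dropped, dropped / sample_rate)
    segments = []
    for k in range(n_segments):
        chunk = samples[k * seg_len:(k + 1) * seg_len].copy()
        peak = np.max(np.abs(chunk))
        if peak > 0:
            chunk /= peak
        segments.append(Segment(samples=chunk, sample_rate=sample_rate,
                                start_time=k * segment_s,
                                recording_id=recording_id, segment_index=k))
    return segments


def preprocess_pipeline(recording: Recording, low_hz: float = 60.0,
                        high_hz: float = 2000.0, bp_order: int = 10,
                        sg_window: int = 9, sg_polyorder: int = 3,
                        dwt_level: int = 4,
                        dwt_threshold: str | float = "universal",
                        segment_s: float = SEGMENT_SECONDS) -> list[Segment]:
    """Full denoising chain for one recording, then segmentation.

    Contact channel: bandpass -> Savitzky-Golay -> wavelet denoise -> segments.
    Air channel: bandpass only (a generic stand-in for a stethoscope's
    built-in pulmonary filter), then segments.
    """
    x = bandpass(recording.samples, recording.sample_rate, low_hz, high_hz,
                 bp_order)
    if recording.channel == "contact":
        x = sgolay_smooth(x, sg_window, sg_polyorder)
        x = wavelet_denoise(x, level=dwt_level, threshold_rule=dwt_threshold)
    logger.info(
        "preprocess %s [%s]: bandpass %g-%g Hz order %d%s",
        recording.recording_id, recording.channel, low_hz, high_hz, bp_order,
        (f", SG window {sg_window}/order {sg_polyorder}, "
         f"db3 level {dwt_level} threshold {dwt_threshold}")
        if recording.channel == "contact" else ", no further smoothing")
    return segment_and_scale(x, recording.sample_rate, segment_s,
                             recording_id=recording.recording_id)


def denoise_only(recording: Recording, **kwargs) -> np.ndarray:
    """The denoising chain without segmentation (for whole-recording analysis)."""
    x = bandpass(recording.samples, recording.sample_rate,
                 kwargs.get("low_hz", 60.0), kwargs.get("high_hz", 2000.0),
                 kwargs.get("bp_order", 10))
    if recording.channel == "contact":
        x = sgolay_smooth(x, kwargs.get("sg_window", 9),
                          kwargs.get("sg_polyorder", 3))
        x = wavelet_denoise(x, level=kwargs.get("dwt_level", 4),
                            threshold_rule=kwargs.get("dwt_threshold", "universal"))
    return x
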