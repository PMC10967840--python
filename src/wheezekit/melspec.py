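"""Mel-spectrogram front end.

STFT framing is explicit and unpadded: frame k covers samples
[k*hop, k*hop + window); frames that would run past the signal are not
computed, so a segment of N samples yields floor((N - window)/hop) + 1
frames.  Frame times refer to frame *centers*, which is what makes detector
onset/offset estimates land within one hop of truth.

The mel axis uses the classic HTK mapping m = 2595 log10(1 + f/700)
(1000 Hz -> ~1000 mel), with 64 triangular bands whose centers are equally
spaced on the mel axis between 60 and 1200 Hz.  Power is expressed in dB
relative to the matrix maximum (0 dB peak) with an -80 dB floor — the usual
display convention for lung-sound spectrograms.

Channel conventions: the contact (accelerometer) channel uses a 1024-sample
Hann window (51.2 ms at 20 kHz); the air channel uses 256 samples at its own
rate.  Both use 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MEL_SCALE = 2595.0
MEL_BREAK_HZ = 700.0
N_BANDS = 64
FMIN_HZ = 60.0
FMAX_HZ = 1200.0
DB_FLOOR = -80.0
CONTACT_WINDOW = 1024
AIR_WINDOW = 256


def mel_scale(f):
    """Hz -> mel: m = 2595 log10(1 + f/700).  Strictly increasing; mel(0)=0."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    return MEL_SCALE * np.log10(1.0 + f / MEL_BREAK_HZ)


def mel_to_hz(m):
    """Inverse of :func:`mel_scale`."""
    m = np.asarray(m, dtype=np.float64)
    return MEL_BREAK_HZ * (10.0 ** (m / MEL_SCALE) - 1.0)


@dataclass
class MelSpectrogram:
    """64-band mel power matrix in dB with axis calibration."""

    power_db: np.ndarray            # (n_bands, n_frames)
    frame_times: np.ndarray         # frame centers, s
    band_center_freqs: np.ndarray   # Hz
    params: dict = field(default_factory=dict)

    @property
    def hop_s(self) -> float:
        return self.params["hop_samples"] / self.params["sample_rate"]

    @property
    def n_frames(self) -> int:
        return self.power_db.shape[1]


def mel_filterbank(sample_rate: float, n_fft: int, n_bands: int = N_BANDS,
                   fmin: float = FMIN_HZ, fmax: float = FMAX_HZ,
                   norm: str = "peak") -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank sampled on the rFFT bin grid.

    Returns (weights of shape (n_bands, n_fft//2 + 1), band center Hz).
    Centers are equally spaced on the mel axis between mel(fmin) and
    mel(fmax); each triangle spans its two neighbouring centers.  ``norm``
    is ``"peak"`` (each triangle peaks at 1) or ``"area"`` (unit area in Hz).
    A triangle too narrow to contain any FFT bin receives unit weight at the
    bin nearest its center so no band is silently dead.
    """
    mel_edges = np.linspace(mel_scale(fmin), mel_scale(fmax), n_bands + 2)
    hz_edges = mel_to_hz(mel_edges)
    centers = hz_edges[1:-1]
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft

    weights = np.zeros((n_bands, bin_freqs.size))
    for b in range(n_bands):
        lo, mid, hi = hz_edges[b], hz_edges[b + 1], hz_edges[b + 2]
        rising = (bin_freqs - lo) / max(mid - lo, 1e-12)
        falling = (hi - bin_freqs) / max(hi - mid, 1e-12)
        tri = np.clip(np.minimum(rising, falling), 0.0, None)
        if not np.any(tri > 0):
            tri[np.argmin(np.abs(bin_freqs - mid))] = 1.0
        if norm == "area":
            tri *= 2.0 / max(hi - lo, 1e-12)
        weights[b] = tri
    return weights, centers


def stft_power(samples: np.ndarray, sample_rate: float, window_samples: int,
               overlap: float = 0.5, window: str = "hann"
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpadded Hann-windowed power spectrogram.

    Returns (power (n_bins, n_frames), bin_freqs Hz, frame center times s).
    """
    samples = np.asarray(samples, dtype=np.float64)
    if window_samples > samples.size:
        raise ValueError(
            f"signal of {samples.size} samples shorter than window {window_samples}")
    hop = int(round(window_samples * (1.0 - overlap)))
    n_frames = (samples.size - window_samples) // hop + 1
    if window == "hann":
        win = np.hanning(window_samples)
    else:
        raise ValueError(f"unsupported window {window!r}")

    idx = np.arange(window_samples)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = samples[idx] * win
    spectrum = np.fft.rfft(frames, n=window_samples, axis=1)
    power = (np.abs(spectrum) ** 2).T
    bin_freqs = np.arange(window_samples // 2 + 1) * sample_rate / window_samples
    frame_times = (hop * np.arange(n_frames) + window_samples / 2) / sample_rate
    return power, bin_freqs, frame_times


def mel_spectrogram(samples: np.ndarray, sample_rate: float,
                    channel: str = "contact", window_samples: int | None = None,
                    overlap: float = 0.5, n_bands: int = N_BANDS,
                    fmin: float = FMIN_HZ, fmax: float = FMAX_HZ,
                    norm: str = "peak", db_floor: float = DB_FLOOR
                    ) -> MelSpectrogram:
    """Compute the calibrated mel spectrogram of a segment or recording.

    The window defaults by channel (contact -> 1024 samples, air -> 256); dB
    is relative to the matrix maximum so any non-silent input peaks at 0 dB.
    A silent input is returned at the uniform floor.
    """
    if window_samples is None:
        window_samples = CONTACT_WINDOW if channel == "contact" else AIR_WINDOW
    power, bin_freqs, frame_times = stft_power(samples, sample_rate,
                                               window_samples, overlap)
    weights, centers = mel_filterbank(sample_rate, window_samples, n_bands,
                                      fmin, fmax, norm)
    mel_power = weights @ power
    peak = mel_power.max()
    if peak > 0:
        power_db = 10.0 * np.log10(np.maximum(mel_power / peak, 10 ** (db_floor / 10)))
    else:
        power_db = np.full_like(mel_power, db_floor)
    hop = int(round(window_samples * (1.0 - overlap)))
    params = {"window_samples": window_samples, "hop_samples": hop,
              "n_bands": n_bands, "fmin": fmin, "fmax": fmax,
              "sample_rate": sample_rate, "channel": channel,
              "norm": norm, "db_floor": db_floor, "db_ref": "matrix max"}
    return MelSpectrogram(power_db=power_db, frame_times=frame_times,
                          band_center_freqs=centers, params=params)
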