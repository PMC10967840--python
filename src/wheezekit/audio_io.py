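"""Waveform and label-table I/O.

Recordings are mono amplitude arrays with an explicit sample rate; nothing in
the package ever resamples implicitly — the contact (accelerometer) channel is
nominally 20 kHz and the air (stethoscope-like) channel may be anything, and
downstream stages take the rate from the :class:`Recording`.

WAV support covers 16- and 24-bit integer PCM: the sensing front end delivers a
24-bit digital stream, while 16-bit suffices for most derived artifacts.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CHANNELS = ("contact", "air")
VALID_LABELS = ("wheeze", "normal")


class AudioFormatError(ValueError):
    """Raised for unreadable or unsupported WAV content."""


@dataclass
class Recording:
    """A mono waveform plus acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        Floating amplitudes, nominally within [-1, 1].
    sample_rate : float
        Sampling rate in Hz; must be positive.
    channel : str
        ``"contact"`` (accelerometer on the chest wall) or ``"air"``
        (airborne-sound microphone).
    site : int or None
        Auscultation site code 1-9, or ``None`` when unknown.
    recording_id : str
        Stable identifier used in manifests and label tables.
    """

    samples: np.ndarray
    sample_rate: float
    channel: str = "contact"
    site: int | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording samples must be mono (1-D)")
        if self.samples.size < 1:
            raise ValueError("Recording must contain at least one sample")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}")
        if self.site is not None and not (1 <= int(self.site) <= 9):
            raise ValueError("site must be an auscultation code in 1..9")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def read_wav(path: str | Path, channel: str = "contact",
             recording_id: str | None = None, site: int | None = None) -> Recording:
    """Read a PCM WAV file into a :class:`Recording`.

    Integer samples are normalized by the format's full scale so the output
    lies in [-1, 1].  Multi-channel files are reduced to their first channel
    with a logged warning.
    """
    path = Path(path)
    try:
        with wave.open(str(path), "rb") as wf:
            n_channels = wf.getnchannels()
            sampwidth = wf.getsampwidth()
            rate = wf.getframerate()
            n_frames = wf.getnframes()
            raw = wf.readframes(n_frames)
    except (wave.Error, EOFError) as exc:
        raise AudioFormatError(f"{path} is not a readable PCM WAV file: {exc}") from exc

    if n_frames < 1:
        raise ValueError(f"{path}: zero-length recording")
    if sampwidth == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(np.float64)
        full_scale = 2 ** 15
    elif sampwidth == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        # sign-extend little-endian 24-bit into int32
        i32 = (b[:, 0].astype(np.int32)
               | (b[:, 1].astype(np.int32) << 8)
               | (b[:, 2].astype(np.int32) << 16))
        i32 = np.where(i32 >= 2 ** 23, i32 - 2 ** 24, i32)
        data = i32.astype(np.float64)
        full_scale = 2 ** 23
    else:
        raise AudioFormatError(
            f"{path}: unsupported sample width {sampwidth * 8} bits (16/24 supported)")

    if n_channels > 1:
        logger.warning("%s has %d channels; keeping the first", path, n_channels)
        data = data.reshape(-1, n_channels)[:, 0]
    return Recording(samples=data / full_scale, sample_rate=float(rate),
                     channel=channel, site=site,
                     recording_id=recording_id or path.stem)


def write_wav(recording: Recording, path: str | Path, bit_depth: int = 16) -> Path:
    """Write a :class:`Recording` to PCM WAV (16- or 24-bit).

    Samples outside [-1, 1] are clipped with a warning; non-finite samples are
    rejected.  ``read_wav(write_wav(r))`` recovers ``r.samples`` within one
    quantization step of the chosen bit depth.
    """
    path = Path(path)
    samples = np.asarray(recording.samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("cannot write an empty recording")
    if not np.all(np.isfinite(samples)):
        raise ValueError("cannot write non-finite samples")
    if np.max(np.abs(samples)) > 1.0:
        logger.warning("write_wav: clipping %d samples outside [-1, 1]",
                       int(np.sum(np.abs(samples) > 1.0)))
        samples = np.clip(samples, -1.0, 1.0)

    if bit_depth == 16:
        full_scale = 2 ** 15
        quantized = np.clip(np.round(samples * full_scale), -full_scale,
                            full_scale - 1).astype("<i2")
        payload = quantized.tobytes()
        sampwidth = 2
    elif bit_depth == 24:
        full_scale = 2 ** 23
        i32 = np.clip(np.round(samples * full_scale), -full_scale,
                      full_scale - 1).astype(np.int32)
        u = (i32 & 0xFFFFFF).astype(np.uint32)
        b = np.empty((u.size, 3), dtype=np.uint8)
        b[:, 0] = u & 0xFF
        b[:, 1] = (u >> 8) & 0xFF
        b[:, 2] = (u >> 16) & 0xFF
        payload = b.tobytes()
        sampwidth = 3
    else:
        raise ValueError("bit_depth must be 16 or 24")

    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(sampwidth)
        wf.setframerate(int(round(recording.sample_rate)))
        wf.writeframes(payload)
    return path


class LabelSchemaError(ValueError):
    """Raised when a label CSV does not match the expected schema."""


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a per-segment label table.

    Expected CSV columns: ``recording_id``, ``segment_index``, ``label`` with
    label values in ``{"wheeze", "normal"}``.  Duplicate
    (recording_id, segment_index) pairs and unknown labels are rejected —
    the classification task is strictly binary.
    """
    table = pd.read_csv(path)
    required = {"recording_id", "segment_index", "label"}
    missing = required - set(table.columns)
    if missing:
        raise LabelSchemaError(f"label table missing columns: {sorted(missing)}")
    bad = set(table["label"].unique()) - set(VALID_LABELS)
    if bad:
        raise LabelSchemaError(f"unknown labels {sorted(bad)}; expected {VALID_LABELS}")
    if table.duplicated(subset=["recording_id", "segment_index"]).any():
        raise LabelSchemaError("duplicate (recording_id, segment_index) rows")
    table = table.astype({"recording_id": str, "segment_index": int, "label": str})
    return table.reset_index(drop=True)


def write_labels(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
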