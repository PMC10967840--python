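"""Synthetic pulmonary-induced-vibration (PIV) scene generator.

No public corpus of chest-wall accelerometer recordings with wheeze labels
exists, so this module synthesizes recordings with the statistical structure
the downstream detectors assume.  A scene is a sum of independently modelled
components, each occupying the band a chest-wall sensor sees it in:

* **chest-wall motion** — a quasi-triangular sub-1 Hz ramp, rising during
  inspiration (upright posture, deep breaths), amplitude ``motion_amplitude``;
* **breath noise** — Gaussian noise band-shaped to 60-1200 Hz and gated by an
  airflow envelope (half-sine per respiration phase, inspiration slightly
  louder than expiration);
* **wheezes** — harmonic tone stacks with a slowly drifting fundamental in
  100-2000 Hz and 1/h harmonic roll-off, amplitude-gated to the requested
  respiration phase with raised-cosine ramps;
* **crackles** — short (<20 ms) exponentially damped tone bursts;
* **heart sounds** — paired (S1/S2) damped low-frequency (<60 Hz) pulses;
* **sensor noise** — a small white floor standing for the thermal noise of
  the MEMS + ASIC front end.

Ambient interference (voices, monitor alarms) never enters the contact
channel: :func:`add_ambient_interference` produces a separate contaminated
"air-microphone" copy, which is how the simulator encodes the contact
sensor's immunity to airborne sound.

All generators are pure functions of (spec, seed): identical inputs yield
bit-identical waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

WHEEZE_BAND_HZ = (100.0, 2000.0)
PHASE_GATES = ("inspiration", "expiration", "both")


class SceneSpecError(ValueError):
    """Raised when a SceneSpec field violates its invariant."""


@dataclass(frozen=True)
class WheezeSpec:
    """One wheeze event: a harmonic stack gated by respiration phase."""

    start: float
    duration: float
    fundamental_hz: float
    drift_hz_per_s: float = 0.0
    n_harmonics: int = 1
    amplitude: float = 0.5
    phase_gate: str = "both"


@dataclass(frozen=True)
class CrackleSpec:
    """One crackle: a damped transient at a point in time."""

    time: float
    amplitude: float = 0.5


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic recording scene.

    Amplitudes are relative units on a common scale; the dominant raw
    component is the sub-1 Hz chest-wall motion, as it is for a DC-coupled
    accelerometer.  ``sensor_noise_level`` is a white noise floor emulating
    front-end thermal noise, and keeps spectrograms away from the degenerate
    all-silent case.
    """

    duration: float = 30.0
    sample_rate: float = 20000.0
    respiration_rate: float = 15.0
    wheeze_events: tuple[WheezeSpec, ...] = ()
    crackle_events: tuple[CrackleSpec, ...] = ()
    heart_rate: float = 70.0
    breath_noise_level: float = 0.2
    motion_amplitude: float = 1.0
    heart_level: float = 0.1
    sensor_noise_level: float = 5e-4
    ambient_level: float = 0.0
    inspiratory_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not self.duration > 0:
            raise SceneSpecError("duration must be > 0")
        if self.sample_rate < 4000:
            raise SceneSpecError("sample_rate must be >= 4 kHz")
        if not 0 < self.inspiratory_fraction < 1:
            raise SceneSpecError("inspiratory_fraction must be in (0, 1)")
        if self.respiration_rate <= 0:
            raise SceneSpecError("respiration_rate must be > 0")
        for name in ("breath_noise_level", "motion_amplitude", "heart_level",
                     "sensor_noise_level", "ambient_level"):
            if getattr(self, name) < 0:
                raise SceneSpecError(f"{name} must be >= 0")
        for w in self.wheeze_events:
            if not WHEEZE_BAND_HZ[0] <= w.fundamental_hz <= WHEEZE_BAND_HZ[1]:
                raise SceneSpecError(
                    f"wheeze_events: fundamental {w.fundamental_hz} Hz outside "
                    f"{WHEEZE_BAND_HZ}")
            if w.start < 0 or w.start + w.duration > self.duration:
                raise SceneSpecError(
                    "wheeze_events: event interval outside [0, duration]")
            if w.phase_gate not in PHASE_GATES:
                raise SceneSpecError(
                    f"wheeze_events: phase_gate must be one of {PHASE_GATES}")
            if w.n_harmonics < 1:
                raise SceneSpecError("wheeze_events: n_harmonics must be >= 1")
        for c in self.crackle_events:
            if not 0 <= c.time <= self.duration:
                raise SceneSpecError("crackle_events: time outside [0, duration]")


@dataclass
class GroundTruth:
    """Exact event and phase annotations for a synthetic recording."""

    wheeze_intervals: list[tuple[float, float, float]] = field(default_factory=list)
    crackle_times: list[float] = field(default_factory=list)
    phase_intervals: list[tuple[float, float, str]] = field(default_factory=list)
    segment_labels: list[bool] = field(default_factory=list)
    segment_s: float = 5.0
    overlap_fraction: float = 0.1


# ---------------------------------------------------------------- components

def respiration_phase_intervals(duration: float, respiration_rate: float,
                                inspiratory_fraction: float = 0.4
                                ) -> list[tuple[float, float, str]]:
    """Tile [0, duration] with alternating inspiration/expiration intervals."""
    period = 60.0 / respiration_rate
    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    while t < duration - 1e-12:
        insp_end = min(t + inspiratory_fraction * period, duration)
        intervals.append((t, insp_end, "inspiration"))
        if insp_end >= duration:
            break
        exp_end = min(t + period, duration)
        intervals.append((insp_end, exp_end, "expiration"))
        t += period
    return intervals


def _chest_motion(t: np.ndarray, intervals, amplitude: float) -> np.ndarray:
    """Quasi-triangular chest-wall displacement: rise in inspiration, fall after."""
    motion = np.zeros_like(t)
    for onset, offset, label in intervals:
        mask = (t >= onset) & (t < offset)
        frac = (t[mask] - onset) / max(offset - onset, 1e-9)
        if label == "inspiration":
            motion[mask] = frac
        else:
            motion[mask] = 1.0 - frac
    # soften the triangle corners a little so it resembles real chest motion
    win_n = max(3, int(0.05 * len(t) / max(t[-1], 1e-9)))
    kernel = np.hanning(win_n + 2)[1:-1]
    kernel /= kernel.sum()
    motion = signal.fftconvolve(motion, kernel, mode="same")
    return amplitude * (motion - motion.mean())


def _phase_mask(t: np.ndarray, intervals, label: str, ramp_s: float = 0.02,
                sample_rate: float = 20000.0) -> np.ndarray:
    mask = np.zeros_like(t)
    for onset, offset, lab in intervals:
        if lab == label:
            mask[(t >= onset) & (t < offset)] = 1.0
    n = max(3, int(ramp_s * sample_rate))
    kernel = np.hanning(n + 2)[1:-1]
    kernel /= kernel.sum()
    return signal.fftconvolve(mask, kernel, mode="same")


def _airflow_envelope(t: np.ndarray, intervals, insp_gain: float = 1.0,
                      exp_gain: float = 0.75) -> np.ndarray:
    """Half-sine airflow magnitude per phase; zero at phase boundaries."""
    env = np.zeros_like(t)
    for onset, offset, label in intervals:
        mask = (t >= onset) & (t < offset)
        frac = (t[mask] - onset) / max(offset - onset, 1e-9)
        gain = insp_gain if label == "inspiration" else exp_gain
        env[mask] = gain * np.sin(np.pi * frac)
    return env


def _breath_noise(rng: np.random.Generator, t: np.ndarray, sample_rate: float,
                  envelope: np.ndarray, level: float) -> np.ndarray:
    noise = rng.standard_normal(t.size)
    low = 60.0 / (sample_rate / 2)
    high = min(1200.0 / (sample_rate / 2), 0.99)
    sos = signal.butter(4, [low, high], btype="bandpass", output="sos")
    shaped = signal.sosfilt(sos, noise)
    shaped /= max(np.std(shaped), 1e-12)
    return level * shaped * envelope


def _wheeze_component(rng: np.random.Generator, t: np.ndarray, sample_rate: float,
                      w: WheezeSpec, intervals) -> np.ndarray:
    out = np.zeros_like(t)
    i0 = int(round(w.start * sample_rate))
    i1 = min(int(round((w.start + w.duration) * sample_rate)), t.size)
    if i1 <= i0:
        return out
    tw = t[i0:i1] - w.start
    f_inst = w.fundamental_hz + w.drift_hz_per_s * tw
    base_phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate
    tone = np.zeros_like(tw)
    for h in range(1, w.n_harmonics + 1):
        phi = rng.uniform(0, 2 * np.pi)
        tone += np.sin(h * base_phase + phi) / h
    # on/off raised-cosine ramps (10 ms) so events have no clicks
    n_ramp = min(int(0.01 * sample_rate), tw.size // 2)
    gate = np.ones_like(tw)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        gate[:n_ramp] = ramp
        gate[-n_ramp:] = ramp[::-1]
    if w.phase_gate != "both":
        gate = gate * _phase_mask(t, intervals, w.phase_gate,
                                  sample_rate=sample_rate)[i0:i1]
    out[i0:i1] = w.amplitude * tone * gate
    return out


def _crackle_component(t: np.ndarray, sample_rate: float, c: CrackleSpec,
                       freq_hz: float = 650.0, tau_s: float = 0.003,
                       length_s: float = 0.015) -> np.ndarray:
    out = np.zeros_like(t)
    i0 = int(round(c.time * sample_rate))
    n = min(int(length_s * sample_rate), t.size - i0)
    if n <= 0:
        return out
    tc = np.arange(n) / sample_rate
    out[i0:i0 + n] = c.amplitude * np.exp(-tc / tau_s) * np.sin(2 * np.pi * freq_hz * tc)
    return out


def _heart_component(t: np.ndarray, sample_rate: float, heart_rate: float,
                     level: float) -> np.ndarray:
    """Paired S1/S2 damped pulses with dominant content below 60 Hz."""
    out = np.zeros_like(t)
    if level == 0 or heart_rate <= 0:
        return out
    beat_period = 60.0 / heart_rate
    n_pulse = int(0.12 * sample_rate)
    tp = np.arange(n_pulse) / sample_rate
    s1 = np.exp(-tp / 0.04) * np.sin(2 * np.pi * 35.0 * tp)
    s2 = 0.6 * np.exp(-tp / 0.03) * np.sin(2 * np.pi * 45.0 * tp)
    t_beat = 0.2
    while t_beat < t[-1]:
        for pulse, offset in ((s1, 0.0), (s2, 0.32)):
            i0 = int(round((t_beat + offset) * sample_rate))
            n = min(n_pulse, t.size - i0)
            if n > 0:
                out[i0:i0 + n] += level * pulse[:n]
        t_beat += beat_period
    return out


# ---------------------------------------------------------------- generators

def _wheeze_truth_intervals(spec: SceneSpec, intervals
                            ) -> list[tuple[float, float, float]]:
    """Audible support of each wheeze: its window intersected with its gate."""
    truth: list[tuple[float, float, float]] = []
    for w in spec.wheeze_events:
        start, end = w.start, w.start + w.duration
        if w.phase_gate == "both":
            pieces = [(start, end)]
        else:
            pieces = []
            for onset, offset, lab in intervals:
                if lab != w.phase_gate:
                    continue
                lo, hi = max(start, onset), min(end, offset)
                if hi - lo > 0.05:  # ignore slivers shorter than the gate ramps
                    pieces.append((lo, hi))
        for lo, hi in pieces:
            mid = 0.5 * (lo + hi)
            truth.append((lo, hi, w.fundamental_hz + w.drift_hz_per_s * (mid - start)))
    return sorted(truth)


def segment_wheeze_labels(wheeze_intervals, duration: float, segment_s: float = 5.0,
                          overlap_fraction: float = 0.1) -> list[bool]:
    """Label each 5 s segment wheeze iff wheeze overlap >= fraction of segment."""
    n_seg = int(duration // segment_s)
    labels = []
    for k in range(n_seg):
        s0, s1 = k * segment_s, (k + 1) * segment_s
        overlap = sum(max(0.0, min(s1, hi) - max(s0, lo))
                      for lo, hi, _ in wheeze_intervals)
        labels.append(overlap >= overlap_fraction * segment_s)
    return labels


def generate_recording(spec: SceneSpec, overlap_fraction: float = 0.1
                       ) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to a waveform and its exact ground truth.

    Deterministic: the same (spec, seed) always yields the same waveform.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    intervals = respiration_phase_intervals(spec.duration, spec.respiration_rate,
                                            spec.inspiratory_fraction)
    envelope = _airflow_envelope(t, intervals)

    waveform = _chest_motion(t, intervals, spec.motion_amplitude)
    waveform += _breath_noise(rng, t, spec.sample_rate, envelope,
                              spec.breath_noise_level)
    for w in spec.wheeze_events:
        waveform += _wheeze_component(rng, t, spec.sample_rate, w, intervals)
    for c in spec.crackle_events:
        waveform += _crackle_component(t, spec.sample_rate, c)
    waveform += _heart_component(t, spec.sample_rate, spec.heart_rate,
                                 spec.heart_level)
    waveform += spec.sensor_noise_level * rng.standard_normal(n)

    wheeze_intervals = _wheeze_truth_intervals(spec, intervals)
    truth = GroundTruth(
        wheeze_intervals=wheeze_intervals,
        crackle_times=[c.time for c in spec.crackle_events],
        phase_intervals=intervals,
        segment_labels=segment_wheeze_labels(wheeze_intervals, spec.duration,
                                             overlap_fraction=overlap_fraction),
        overlap_fraction=overlap_fraction,
    )
    return waveform, truth


def add_ambient_interference(waveform: np.ndarray, level: float, seed: int,
                             sample_rate: float = 20000.0) -> np.ndarray:
    """Mix speech-like and alarm-like ambient interference into a waveform.

    The interference is what an air microphone picks up in a noisy ward:
    amplitude-modulated formant-like tone complexes (syllables, centers in
    100-1200 Hz) plus an intermittent fixed-frequency monitor alarm.  The
    contact channel never passes through this function — only the
    "air-microphone" copy of a scene does.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    waveform = np.asarray(waveform, dtype=np.float64)
    if level == 0:
        return waveform.copy()
    rng = np.random.default_rng(seed)
    n = waveform.size
    t = np.arange(n) / sample_rate
    interference = np.zeros(n)

    # voice-like syllables: ~3/s, each 120-280 ms, 2-3 formant tones
    t_syl = rng.uniform(0.0, 0.4)
    while t_syl < t[-1]:
        dur = rng.uniform(0.12, 0.28)
        i0 = int(t_syl * sample_rate)
        m = min(int(dur * sample_rate), n - i0)
        if m > 8:
            ts = np.arange(m) / sample_rate
            env = np.sin(np.pi * ts / dur) ** 2
            syllable = np.zeros(m)
            for _ in range(rng.integers(2, 4)):
                f = rng.uniform(100.0, 1200.0)
                syllable += rng.uniform(0.3, 1.0) * np.sin(
                    2 * np.pi * f * ts + rng.uniform(0, 2 * np.pi))
            interference[i0:i0 + m] += env * syllable
        t_syl += rng.uniform(0.2, 0.5)

    # monitor alarm: 900 Hz beeps, 150 ms, once per second with 50% duty
    beep_n = int(0.15 * sample_rate)
    tb = np.arange(beep_n) / sample_rate
    beep = np.sin(2 * np.pi * 900.0 * tb) * np.hanning(beep_n)
    for second in range(int(np.ceil(t[-1]))):
        if rng.random() < 0.5:
            i0 = int(second * sample_rate)
            m = min(beep_n, n - i0)
            interference[i0:i0 + m] += 0.8 * beep[:m]

    rms = np.sqrt(np.mean(interference ** 2))
    if rms > 0:
        interference *= 1.0 / rms
    return waveform + level * interference


def generate_corpus(n_recordings: int, class_mix: Sequence[float],
                    base_spec: SceneSpec, seed: int,
                    amplitude_range: tuple[float, float] = (0.3, 0.7),
                    ) -> tuple[list[SceneSpec], list[np.ndarray], list[GroundTruth]]:
    """Generate a labeled corpus of recordings.

    ``class_mix`` gives fractions over (wheeze, normal, mixed) recordings and
    must sum to 1.  Wheeze recordings place one expiration-gated harmonic
    stack in every breath cycle; mixed recordings wheeze only in the first
    half; normal recordings contain no wheeze.  Wheeze fundamentals are drawn
    uniformly in 150-900 Hz and amplitudes log-uniformly in
    ``amplitude_range`` (relative to the scene's breath-noise level ~0.2),
    so the corpus spans faint to loud wheezes.

    Per-recording seeds are derived deterministically from ``seed``.
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.size != 3 or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("class_mix must be 3 nonnegative fractions summing to 1")

    counts = np.floor(mix * n_recordings).astype(int)
    order = np.argsort(-(mix * n_recordings - counts))
    for i in range(n_recordings - counts.sum()):
        counts[order[i % 3]] += 1
    classes = (["wheeze"] * counts[0] + ["normal"] * counts[1]
               + ["mixed"] * counts[2])

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n_recordings)
    intervals = respiration_phase_intervals(base_spec.duration,
                                            base_spec.respiration_rate,
                                            base_spec.inspiratory_fraction)
    exp_intervals = [(a, b) for a, b, lab in intervals if lab == "expiration"]

    specs, waveforms, truths = [], [], []
    for cls, child_seed in zip(classes, child_seeds):
        rng = np.random.default_rng(child_seed)
        wheezes: list[WheezeSpec] = []
        if cls != "normal":
            usable = exp_intervals
            if cls == "mixed":
                usable = [iv for iv in exp_intervals
                          if iv[1] <= base_spec.duration / 2]
            for onset, offset in usable:
                span = offset - onset
                dur = rng.uniform(0.6, 0.9) * span
                start = onset + rng.uniform(0.0, span - dur)
                lo, hi = amplitude_range
                amp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                wheezes.append(WheezeSpec(
                    start=start, duration=dur,
                    fundamental_hz=float(rng.uniform(150.0, 900.0)),
                    drift_hz_per_s=float(rng.uniform(-20.0, 20.0)),
                    n_harmonics=int(rng.integers(1, 4)),
                    amplitude=amp, phase_gate="expiration"))
        crackles = tuple(
            CrackleSpec(time=float(rng.uniform(0, base_spec.duration)),
                        amplitude=float(rng.uniform(0.2, 0.5)))
            for _ in range(rng.integers(0, 3)))
        spec = replace(base_spec, wheeze_events=tuple(wheezes),
                       crackle_events=crackles, seed=int(child_seed))
        waveform, truth = generate_recording(spec)
        specs.append(spec)
        waveforms.append(waveform)
        truths.append(truth)
    return specs, waveforms, truths
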