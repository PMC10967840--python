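import numpy as np
import pytest

from wheezekit.synthetic import (CrackleSpec, SceneSpec, SceneSpecError,
                                 WheezeSpec, add_ambient_interference,
                                 generate_corpus, generate_recording)


def quiet_spec(**kwargs):
    """A scene with every component silenced unless overridden."""
    defaults = dict(duration=10.0, breath_noise_level=0.0, motion_amplitude=0.0,
                    heart_level=0.0, sensor_noise_level=0.0, seed=0)
    defaults.update(kwargs)
    return SceneSpec(**defaults)


def test_single_wheeze_echoed_in_truth():
    spec = quiet_spec(wheeze_events=(
        WheezeSpec(start=2.0, duration=0.5, fundamental_hz=400.0),))
    waveform, truth = generate_recording(spec)
    assert waveform.size == int(10.0 * spec.sample_rate)
    assert len(truth.wheeze_intervals) == 1
    lo, hi, f0 = truth.wheeze_intervals[0]
    assert (lo, hi, f0) == (2.0, 2.5, 400.0)


def test_phase_interval_counts():
    spec = SceneSpec(duration=60.0, respiration_rate=15.0, seed=0)
    _, truth = generate_recording(spec)
    labels = [lab for _, _, lab in truth.phase_intervals]
    assert labels.count("inspiration") == 15
    assert labels.count("expiration") == 15
    # intervals tile [0, duration]
    edges = np.array([(a, b) for a, b, _ in truth.phase_intervals])
    assert edges[0, 0] == 0.0 and edges[-1, 1] == 60.0
    assert np.allclose(edges[1:, 0], edges[:-1, 1])


def test_recording_determinism():
    spec = SceneSpec(duration=5.0, seed=42, wheeze_events=(
        WheezeSpec(start=1.0, duration=1.0, fundamental_hz=300.0),))
    w1, _ = generate_recording(spec)
    w2, _ = generate_recording(spec)
    assert np.max(np.abs(w1 - w2)) == 0.0


def test_spec_validation_names_field():
    with pytest.raises(SceneSpecError, match="duration"):
        SceneSpec(duration=-1.0).validate()
    with pytest.raises(SceneSpecError, match="fundamental"):
        SceneSpec(duration=5.0, wheeze_events=(
            WheezeSpec(start=0, duration=1, fundamental_hz=50.0),)).validate()
    with pytest.raises(SceneSpecError, match="crackle"):
        SceneSpec(duration=5.0, crackle_events=(
            CrackleSpec(time=9.0),)).validate()
    with pytest.raises(SceneSpecError, match="sample_rate"):
        SceneSpec(duration=5.0, sample_rate=1000.0).validate()


def test_wheeze_band_occupancy():
    """With only a wheeze enabled, energy concentrates at the harmonic stack."""
    spec = quiet_spec(wheeze_events=(
        WheezeSpec(start=1.0, duration=6.0, fundamental_hz=400.0,
                   n_harmonics=3, amplitude=1.0),))
    waveform, _ = generate_recording(spec)
    spectrum = np.abs(np.fft.rfft(waveform)) ** 2
    freqs = np.fft.rfftfreq(waveform.size, 1 / spec.sample_rate)
    near_stack = np.zeros_like(freqs, dtype=bool)
    for h in (1, 2, 3):
        near_stack |= np.abs(freqs - 400.0 * h) <= 20.0
    assert spectrum[near_stack].sum() / spectrum.sum() >= 0.90


def test_expiration_gating_suppresses_inspiration_energy():
    spec = quiet_spec(duration=20.0, respiration_rate=15.0, wheeze_events=(
        WheezeSpec(start=0.0, duration=20.0, fundamental_hz=500.0,
                   phase_gate="expiration", amplitude=1.0),))
    waveform, truth = generate_recording(spec)
    t = np.arange(waveform.size) / spec.sample_rate
    energy = waveform ** 2
    insp = np.zeros_like(t, dtype=bool)
    for a, b, lab in truth.phase_intervals:
        if lab == "inspiration":
            insp |= (t >= a) & (t < b)
    assert energy[insp].sum() < 0.05 * energy.sum()


def test_crackles_are_short_transients():
    spec = quiet_spec(crackle_events=(CrackleSpec(time=3.0, amplitude=1.0),))
    waveform, truth = generate_recording(spec)
    nonzero = np.flatnonzero(np.abs(waveform) > 1e-6)
    assert truth.crackle_times == [3.0]
    assert (nonzero[-1] - nonzero[0]) / spec.sample_rate < 0.020


def test_ambient_level_zero_is_identity(rng):
    x = rng.standard_normal(1000)
    assert np.array_equal(add_ambient_interference(x, 0.0, seed=1), x)


def test_ambient_determinism_and_band(rng):
    silence = np.zeros(int(5 * 20000))
    a1 = add_ambient_interference(silence, 1.0, seed=9)
    a2 = add_ambient_interference(silence, 1.0, seed=9)
    assert np.array_equal(a1, a2)
    assert np.any(a1 != 0)
    # spectral peaks of the interference land in the speech/alarm band
    from wheezekit.melspec import stft_power
    power, freqs, _ = stft_power(a1, 20000, 1024)
    loud = power.max(axis=0) > 0.01 * power.max()
    peak_freqs = freqs[np.argmax(power[:, loud], axis=0)]
    in_band = (peak_freqs >= 100.0) & (peak_freqs <= 1200.0)
    assert in_band.mean() > 0.9


def test_corpus_class_construction():
    base = SceneSpec(duration=10.0, sample_rate=4000.0)
    specs, waves, truths = generate_corpus(10, (0.5, 0.5, 0.0), base, seed=3)
    n_wheeze = sum(len(t.wheeze_intervals) > 0 for t in truths)
    assert n_wheeze == 5
    assert all(w.size == int(10.0 * 4000) for w in waves)
    # determinism of the label multiset
    _, _, truths2 = generate_corpus(10, (0.5, 0.5, 0.0), base, seed=3)
    labels1 = sorted(tuple(t.segment_labels) for t in truths)
    labels2 = sorted(tuple(t.segment_labels) for t in truths2)
    assert labels1 == labels2


def test_corpus_rejects_bad_arguments():
    base = SceneSpec(duration=10.0, sample_rate=4000.0)
    with pytest.raises(ValueError):
        generate_corpus(0, (0.5, 0.5, 0.0), base, seed=0)
    with pytest.raises(ValueError):
        generate_corpus(4, (0.9, 0.5, 0.0), base, seed=0)


def test_segment_labels_follow_overlap_rule():
    """Wheeze segments overlap a wheeze >= the fraction; normals do not."""
    base = SceneSpec(duration=20.0, sample_rate=4000.0)
    _, _, truths = generate_corpus(6, (0.5, 0.5, 0.0), base, seed=13)
    for truth in truths:
        for k, flag in enumerate(truth.segment_labels):
            s0, s1 = k * 5.0, (k + 1) * 5.0
            overlap = sum(max(0.0, min(s1, hi) - max(s0, lo))
                          for lo, hi, _ in truth.wheeze_intervals)
            if flag:
                assert overlap >= truth.overlap_fraction * 5.0
            else:
                assert overlap < truth.overlap_fraction * 5.0
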