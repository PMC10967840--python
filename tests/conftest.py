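"""Shared fixtures.

The two corpus fixtures are session-scoped because synthesizing recordings
and training the numpy CNN dominate suite runtime; every test that needs a
trained model or a benchmark table reuses the same deterministic corpus.
"""

from __future__ import annotations

import numpy as np
import pytest

import wheezekit as wk
from wheezekit import classifier as clf
from wheezekit.benchmark import build_benchmark_corpus, run_benchmark


SR_CONTACT = 20000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone_segment(t0: float, dur: float, f0: float = 400.0,
                 sample_rate: float = SR_CONTACT, seconds: float = 5.0,
                 noise: float = 5e-4, seed: int = 0) -> np.ndarray:
    """A 5 s segment: one tone burst over a small sensor-noise floor."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(seconds * sample_rate)) / sample_rate
    x = noise * rng.standard_normal(t.size)
    m = (t >= t0) & (t < t0 + dur)
    x[m] += 0.5 * np.sin(2 * np.pi * f0 * t[m])
    return x / np.max(np.abs(x))


@pytest.fixture(scope="session")
def separable_corpus():
    """~430 labeled segments with clearly audible wheezes (8 kHz scenes).

    Loud harmonic stacks (amplitude 0.3-0.7 vs breath noise 0.2) make the
    two classes separable by construction; used for classifier sanity checks.
    """
    base = wk.SceneSpec(duration=30.0, sample_rate=8000.0,
                        respiration_rate=15.0)
    _, waves, truths = wk.generate_corpus(72, (0.5, 0.5, 0.0), base, seed=21,
                                          amplitude_range=(0.3, 0.7))
    melspecs, labels, groups = [], [], []
    for g, (w, tr) in enumerate(zip(waves, truths)):
        rec = wk.Recording(samples=w, sample_rate=base.sample_rate,
                           channel="contact", recording_id=f"r{g:03d}")
        for k, seg in enumerate(wk.preprocess_pipeline(rec)):
            melspecs.append(wk.mel_spectrogram(seg.samples, seg.sample_rate,
                                               channel="contact"))
            labels.append(tr.segment_labels[k])
            groups.append(g)
    x = clf.spectrogram_features(melspecs)
    return x, np.asarray(labels, dtype=int), np.asarray(groups)


@pytest.fixture(scope="session")
def separable_cv_report(separable_corpus):
    """Five-fold CV + test evaluation of the CNN on the separable corpus."""
    x, y, groups = separable_corpus
    config = clf.ModelConfig(seed=21, max_epochs=10, patience=3,
                             batch_size=16)
    pool_idx, test_idx = clf.split_dataset(y, 0.2, seed=21, groups=groups)
    report = clf.cross_validate(x[pool_idx], y[pool_idx], x[test_idx],
                                y[test_idx], config, groups=groups[pool_idx])
    return report, (x, y, groups, pool_idx, test_idx)


@pytest.fixture(scope="session")
def benchmark_results():
    """Contact-vs-air, TF-vs-CNN table on a mixed-SNR 20 kHz corpus.

    Wheeze amplitudes span 0.25-0.6 (log-uniform) against breath noise 0.2;
    ambient interference at level 1.0 contaminates only the air channel.
    The CNN schedule allows for the optimization plateau this architecture
    shows before its loss breaks away from chance.
    """
    base = wk.SceneSpec(duration=30.0, sample_rate=SR_CONTACT,
                        respiration_rate=15.0)
    corpus = build_benchmark_corpus(36, base, seed=7, ambient_level=1.0,
                                    amplitude_range=(0.25, 0.6))
    config = clf.ModelConfig(seed=7, max_epochs=15, patience=8, batch_size=16)
    table, reports = run_benchmark(corpus, config)
    return table, reports, corpus
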