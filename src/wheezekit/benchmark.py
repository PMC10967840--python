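"""End-to-end benchmark: time-frequency detector vs CNN, contact vs air.

Builds a synthetic corpus, derives a contaminated "air-microphone" copy of
every recording (ambient interference never touches the contact channel),
runs both detection methods per channel on the identical held-out test
segments, and emits a four-row comparison table:

    contact / time-frequency
    contact / cnn
    air     / time-frequency
    air     / cnn

each scored for accuracy, sensitivity, specificity, ROC AUC and PR AUC.
The time-frequency method needs no training; its AUC uses the longest
linked-track duration as a continuous score.  The CNN is trained per channel
on that channel's training pool (one fit with an early-stopping carve-out,
mirroring how the two sensors' models were fit separately in practice);
cross-validated evaluation lives in :mod:`wheezekit.classifier`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from .audio_io import Recording
from .detector import DetectorConfig, detect_wheezes, link_tracks, frame_peaks
from .melspec import MelSpectrogram, mel_spectrogram
from .preprocess import preprocess_pipeline
from .synthetic import SceneSpec, generate_corpus, add_ambient_interference


@dataclass
class BenchmarkCorpus:
    """Per-segment features and labels for both channels of one corpus."""

    labels: np.ndarray                       # bool per segment
    groups: np.ndarray                       # recording index per segment
    contact_melspecs: list[MelSpectrogram] = field(default_factory=list)
    air_melspecs: list[MelSpectrogram] = field(default_factory=list)


def tf_score(melspec: MelSpectrogram, config: DetectorConfig) -> float:
    """Longest linked-track duration (s) — a threshold-free wheeze score."""
    tracks = link_tracks(frame_peaks(melspec, config), config)
    if not tracks:
        return 0.0
    return max((pts[-1][0] - pts[0][0]) * melspec.hop_s for pts in tracks)


def build_benchmark_corpus(n_recordings: int, base_spec: SceneSpec, seed: int,
                           class_mix=(0.5, 0.5, 0.0), ambient_level: float = 1.0,
                           amplitude_range: tuple[float, float] = (0.08, 0.5),
                           ) -> BenchmarkCorpus:
    """Synthesize a corpus and preprocess both channels into mel spectrograms."""
    _, waveforms, truths = generate_corpus(
        n_recordings, class_mix, base_spec, seed,
        amplitude_range=amplitude_range)
    air_rng = np.random.default_rng(seed + 1)

    labels, groups = [], []
    contact_ms, air_ms = [], []
    for rec_idx, (waveform, truth) in enumerate(zip(waveforms, truths)):
        contact = Recording(samples=waveform, sample_rate=base_spec.sample_rate,
                            channel="contact", recording_id=f"rec{rec_idx:03d}")
        air_wave = add_ambient_interference(
            waveform, ambient_level, seed=int(air_rng.integers(0, 2 ** 31 - 1)),
            sample_rate=base_spec.sample_rate)
        air = Recording(samples=air_wave, sample_rate=base_spec.sample_rate,
                        channel="air", recording_id=f"rec{rec_idx:03d}")
        contact_segments = preprocess_pipeline(contact)
        air_segments = preprocess_pipeline(air)
        for k, (cseg, aseg) in enumerate(zip(contact_segments, air_segments)):
            labels.append(truth.segment_labels[k])
            groups.append(rec_idx)
            contact_ms.append(mel_spectrogram(cseg.samples, cseg.sample_rate,
                                              channel="contact"))
            air_ms.append(mel_spectrogram(aseg.samples, aseg.sample_rate,
                                          channel="air"))
    return BenchmarkCorpus(labels=np.asarray(labels, dtype=bool),
                           groups=np.asarray(groups),
                           contact_melspecs=contact_ms, air_melspecs=air_ms)


def run_benchmark(corpus: BenchmarkCorpus, config: clf.ModelConfig,
                  detector_config: DetectorConfig | None = None,
                  test_fraction: float = 0.2, grouped: bool = True
                  ) -> tuple[pd.DataFrame, dict]:
    """Score all four (channel, method) combinations on one shared test set."""
    detector_config = detector_config or DetectorConfig()
    y = corpus.labels.astype(int)
    groups = corpus.groups if grouped else None
    pool_idx, test_idx = clf.split_dataset(y, test_fraction=test_fraction,
                                           seed=config.seed, groups=groups)

    rows, reports = [], {}
    for channel, melspecs in (("contact", corpus.contact_melspecs),
                              ("air", corpus.air_melspecs)):
        # deterministic time-frequency method on the test segments
        flags = np.array([detect_wheezes(melspecs[i], detector_config)[1]
                          for i in test_idx])
        scores = np.array([tf_score(melspecs[i], detector_config)
                           for i in test_idx])
        tf_metrics = clf.scores_to_metrics(flags.astype(float), y[test_idx])
        auc_metrics = clf.scores_to_metrics(scores, y[test_idx])
        tf_metrics["roc_auc"] = auc_metrics["roc_auc"]
        tf_metrics["pr_auc"] = auc_metrics["pr_auc"]
        rows.append({"channel": channel, "method": "time-frequency",
                     **tf_metrics})

        x = clf.spectrogram_features(melspecs)
        tr_idx, val_idx = clf.split_dataset(y[pool_idx], test_fraction=0.1,
                                            seed=config.seed)
        model = clf.build_model(config, x.shape[2:])
        history = clf.train(model, x[pool_idx][tr_idx], y[pool_idx][tr_idx],
                            x[pool_idx][val_idx], y[pool_idx][val_idx],
                            config)
        cnn_metrics = clf.evaluate(model, x[test_idx], y[test_idx])
        reports[channel] = {"history": history, "test": cnn_metrics,
                            "n_pool": int(pool_idx.size),
                            "n_test": int(test_idx.size)}
        rows.append({"channel": channel, "method": "cnn", **cnn_metrics})

    table = pd.DataFrame(rows)[
        ["channel", "method", "accuracy", "sensitivity", "specificity",
         "roc_auc", "pr_auc"]]
    # row order: contact TF, contact CNN, air TF, air CNN
    return table, reports
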