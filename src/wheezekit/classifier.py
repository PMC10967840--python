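"""2D convolutional wheeze classifier: architecture, splits, training, metrics.

Architecture (valid 3x3 convolutions, i.e. no padding):

    [conv(32) -> ReLU -> dropout 0.25 -> maxpool 2x2] x {32, 64, 128, 256}
    -> flatten -> dense(128, ReLU) -> dropout 0.5 -> dense(1) -> sigmoid

trained with Adam (lr 0.001) on binary cross-entropy, early stopping on
validation loss.  Inputs are per-spectrogram standardized dB matrices.

The evaluation protocol holds out a stratified 20% test set, runs five-fold
cross-validation on the remaining pool, then refits on the pool and scores
the test set once.  Splits can optionally be grouped by recording so
segments of one recording never straddle train/test — the conservative
choice when segments within a recording are correlated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import auc, precision_recall_curve, roc_curve
from sklearn.model_selection import (StratifiedGroupKFold, StratifiedKFold,
                                     StratifiedShuffleSplit)

from . import nn
from .melspec import MelSpectrogram


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier (defaults follow the method)."""

    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel: tuple[int, int] = (3, 3)
    conv_dropout: float = 0.25
    pool: tuple[int, int] = (2, 2)
    dense_width: int = 128
    dense_dropout: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError("exactly four convolution blocks are required")
        for rate in (self.conv_dropout, self.dense_dropout):
            if not 0 < rate < 1:
                raise ValueError("dropout rates must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class EvalReport:
    """Per-fold and test-set metrics plus the exact protocol state."""

    folds: list[dict] = field(default_factory=list)
    fold_mean: dict = field(default_factory=dict)
    test: dict = field(default_factory=dict)
    fold_assignments: list[list[int]] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# ----------------------------------------------------------------- features

def spectrogram_features(melspecs: list[MelSpectrogram]) -> np.ndarray:
    """Stack spectrograms into (N, 1, bands, frames) float32 inputs.

    Each dB matrix is standardized independently (zero mean, unit variance)
    — the only input normalization applied.
    """
    mats = []
    for ms in melspecs:
        m = ms.power_db.astype(np.float32)
        std = m.std()
        mats.append((m - m.mean()) / (std if std > 0 else 1.0))
    return np.stack(mats)[:, None, :, :]


# ------------------------------------------------------------------- splits

def split_dataset(labels, test_fraction: float = 0.2, seed: int = 0,
                  groups=None) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (optionally group-aware) train/test index split.

    Returns (train_idx, test_idx): disjoint, exhaustive, deterministic for a
    fixed seed.  With ``groups`` given, whole groups (recordings) go to one
    side, at the cost of only approximate stratification.
    """
    y = np.asarray(labels).astype(int)
    if y.size < 10:
        raise ValueError("need at least 10 labeled segments to split")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if groups is None:
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                          random_state=seed)
        train_idx, test_idx = next(splitter.split(np.zeros_like(y), y))
    else:
        # stratified *and* grouped: carve the test side out as one fold of a
        # label-stratified group k-fold so both sides keep the class balance
        n_splits = max(2, int(round(1.0 / test_fraction)))
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                        random_state=seed)
        train_idx, test_idx = next(splitter.split(np.zeros_like(y), y, groups))
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError("grouped split left a side single-class; "
                             "use more recordings or a different seed")
    return np.sort(train_idx), np.sort(test_idx)


def kfold_indices(labels, k: int = 5, seed: int = 0, groups=None
                  ) -> list[np.ndarray]:
    """Stratified k folds (validation indices), near-equal and exhaustive."""
    y = np.asarray(labels).astype(int)
    if k > y.size:
        raise ValueError(f"k={k} exceeds pool size {y.size}")
    if groups is None:
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [np.sort(val) for _, val in kf.split(np.zeros_like(y), y)]
    kf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return [np.sort(val) for _, val in kf.split(np.zeros_like(y), y, groups)]


# -------------------------------------------------------------------- model

def feature_map_sizes(input_shape: tuple[int, int],
                      config: ModelConfig | None = None
                      ) -> list[tuple[int, int]]:
    """Spatial size after each conv+pool block (valid conv, floor pooling)."""
    config = config or ModelConfig()
    h, w = input_shape
    sizes = []
    for _ in config.conv_filters:
        h, w = nn.conv2d_output_shape(h, w, config.kernel)
        if h < 1 or w < 1:
            raise nn.ShapeError(
                f"input too small: conv block {len(sizes) + 1} would produce "
                f"{h}x{w}")
        h, w = nn.pool2d_output_shape(h, w, config.pool)
        if h < 1 or w < 1:
            raise nn.ShapeError(
                f"input too small: pool block {len(sizes) + 1} would produce "
                f"{h}x{w}")
        sizes.append((h, w))
    return sizes


def build_model(config: ModelConfig, input_shape: tuple[int, int]
                ) -> nn.Sequential:
    """Assemble the four-block CNN for inputs of (bands, frames)."""
    sizes = feature_map_sizes(input_shape, config)   # raises ShapeError early
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for i, filters in enumerate(config.conv_filters):
        layers += [nn.Conv2D(in_ch, filters, config.kernel, rng,
                             needs_input_grad=i > 0),
                   nn.ReLU(),
                   nn.Dropout(config.conv_dropout),
                   nn.MaxPool2D(config.pool)]
        in_ch = filters
    flat = sizes[-1][0] * sizes[-1][1] * config.conv_filters[-1]
    layers += [nn.Flatten(),
               nn.Dense(flat, config.dense_width, rng),
               nn.ReLU(),
               nn.Dropout(config.dense_dropout),
               nn.Dense(config.dense_width, 1, rng)]
    return nn.Sequential(layers)


def train(model: nn.Sequential, x_train, y_train, x_val, y_val,
          config: ModelConfig) -> nn.TrainHistory:
    """Train with Adam + early stopping; restores best-validation weights."""
    return nn.fit(model, x_train, y_train, x_val, y_val,
                  learning_rate=config.learning_rate,
                  batch_size=config.batch_size, max_epochs=config.max_epochs,
                  patience=config.patience, seed=config.seed)


# ------------------------------------------------------------------ metrics

def evaluate(model: nn.Sequential, x, y, threshold: float = 0.5) -> dict:
    """Hard metrics at ``threshold`` plus trapezoidal ROC and PR AUC."""
    scores = nn.predict_proba(model, x)
    return scores_to_metrics(scores, y, threshold)


def scores_to_metrics(scores, y, threshold: float = 0.5) -> dict:
    y = np.asarray(y).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    metrics = {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
    }
    if n_pos and n_neg:
        fpr, tpr, _ = roc_curve(y, scores)
        metrics["roc_auc"] = float(auc(fpr, tpr))
        precision, recall, _ = precision_recall_curve(y, scores)
        metrics["pr_auc"] = float(auc(recall, precision))
    else:
        warnings.warn("single-class data: AUC undefined", stacklevel=2)
        metrics["roc_auc"] = float("nan")
        metrics["pr_auc"] = float("nan")
    return metrics


def cross_validate(x_pool, y_pool, x_test, y_test, config: ModelConfig,
                   groups=None, k: int = 5) -> EvalReport:
    """Five-fold CV on the pool, then a final fit scored once on the test set.

    Each fold trains on the other folds with the held-out fold as the early
    stopping validation set.  The final model refits on the whole pool (with
    a 10% carve-out for early stopping) before the single test evaluation.
    """
    input_shape = x_pool.shape[2:]
    folds = kfold_indices(y_pool, k=k, seed=config.seed, groups=groups)
    report = EvalReport(config=asdict(config), seed=config.seed,
                        fold_assignments=[f.tolist() for f in folds])
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y_pool)), val_idx)
        model = build_model(config, input_shape)
        train(model, x_pool[train_idx], y_pool[train_idx],
              x_pool[val_idx], y_pool[val_idx], config)
        report.folds.append(evaluate(model, x_pool[val_idx], y_pool[val_idx]))

    keys = report.folds[0].keys()
    report.fold_mean = {k_: float(np.nanmean([f[k_] for f in report.folds]))
                        for k_ in keys}

    # early-stopping carve-out only; grouping is not needed here because the
    # validation split is never reported as an evaluation result
    tr_idx, val_idx = split_dataset(y_pool, test_fraction=0.1,
                                    seed=config.seed)
    final = build_model(config, input_shape)
    train(final, x_pool[tr_idx], y_pool[tr_idx], x_pool[val_idx],
          y_pool[val_idx], config)
    report.test = evaluate(final, x_test, y_test)
    return report
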