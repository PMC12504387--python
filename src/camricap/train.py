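"""Training integration and evaluation metrics.

Each epoch shuffles the training set, forms mini-batches and, after an
optional warm-up period, replaces every batch with CAM-guided composites
before the optimisation step.  The loss is soft-label cross-entropy
``-sum_c ybar_c log softmax(z)_c``, the standard choice for mixed-sample
augmentation where the target is a probability vector rather than a single
class.  Warm-up epochs train on clean images so that the network providing
the CAMs is not pure noise when mixing starts; evaluation always uses
clean, unaugmented images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .adapters import TinyCnnAdapter
from .compose import AugmentConfig, classic_ricap, enhanced_ricap
from .data import LeafDataset
from .errors import ConfigError, TrainingDivergedError, ValidationError

AUGMENTATIONS = ("none", "enhanced_ricap", "classic_ricap")


@dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    Defaults follow the reference setting for fine-tuning large backbones
    (Adam, learning rate 1e-4, weight decay 1e-5); the bundled tiny CNN
    trained from scratch benefits from a larger rate (the demo configs use
    3e-3).
    """

    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    optimizer: str = "adam"
    epochs: int = 5
    batch_size: int = 16
    augmentation: str = "enhanced_ricap"
    cam_warmup_epochs: int = 1
    seed: int = 0
    gamma_min: float = 0.25
    gamma_max: float = 0.75
    layout: str = "quadrant_resize"
    ricap_beta: float = 0.3

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not 0 <= self.cam_warmup_epochs <= self.epochs:
            raise ConfigError("cam_warmup_epochs must lie in [0, epochs]")
        if self.augmentation not in AUGMENTATIONS:
            raise ConfigError(f"augmentation must be one of {AUGMENTATIONS}")

    def augment_config(self) -> AugmentConfig:
        return AugmentConfig(self.gamma_min, self.gamma_max, self.layout)


@dataclass
class EpochStats:
    epoch: int
    mean_loss: float
    samples_seen: int
    augmented: bool
    mean_lambda_max: Optional[float] = None  # avg of max label weight per composite


def soft_cross_entropy(logits: np.ndarray, soft_label: np.ndarray) -> float:
    """Cross-entropy of a soft target against softmax(logits), stabilised."""
    logits = np.asarray(logits, dtype=float)
    soft_label = np.asarray(soft_label, dtype=float)
    if logits.shape != soft_label.shape:
        raise ValidationError(f"shape mismatch: logits {logits.shape} vs label {soft_label.shape}")
    shifted = logits - logits.max()
    log_probs = shifted - np.log(np.exp(shifted).sum())
    return float(-(soft_label * log_probs).sum())


def _onehot(labels: Sequence[int], num_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), num_classes))
    out[np.arange(len(labels)), list(labels)] = 1.0
    return out


def train_epoch(
    adapter: TinyCnnAdapter,
    dataset: LeafDataset,
    config: TrainConfig,
    rng_shuffle: np.random.Generator,
    rng_augment: np.random.Generator,
    apply_augmentation: bool,
) -> EpochStats:
    """One pass over the dataset; returns mean loss and sample count.

    ``rng_shuffle`` orders the data; ``rng_augment`` drives the mixer.  A
    warm-up (or ``augmentation='none'``) epoch never touches
    ``rng_augment``, so warm-up-only runs are bit-identical to unaugmented
    ones at equal seeds.
    """
    order = rng_shuffle.permutation(len(dataset))
    losses: List[float] = []
    lambda_maxes: List[float] = []
    seen = 0
    for start in range(0, len(order), config.batch_size):
        batch_idx = order[start : start + config.batch_size]
        batch = [dataset[i] for i in batch_idx]
        if apply_augmentation and config.augmentation == "enhanced_ricap":
            mixed = enhanced_ricap(batch, adapter, config.augment_config(),
                                   rng_augment, dataset.num_classes)
            images = np.stack([m.image for m in mixed])
            targets = np.stack([m.soft_label for m in mixed])
            lambda_maxes.extend(float(m.soft_label.max()) for m in mixed)
        elif apply_augmentation and config.augmentation == "classic_ricap":
            mixed = classic_ricap(batch, config.ricap_beta, rng_augment,
                                  dataset.num_classes)
            images = np.stack([m.image for m in mixed])
            targets = np.stack([m.soft_label for m in mixed])
        else:
            images = np.stack([s.image for s in batch])
            targets = _onehot([s.label for s in batch], dataset.num_classes)
        loss = adapter.train_step(images, targets)
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at batch starting {start} (seed {config.seed})"
            )
        losses.append(loss)
        seen += len(batch)
    return EpochStats(
        epoch=-1,
        mean_loss=float(np.mean(losses)),
        samples_seen=seen,
        augmented=apply_augmentation,
        mean_lambda_max=float(np.mean(lambda_maxes)) if lambda_maxes else None,
    )


def train(
    adapter: TinyCnnAdapter,
    dataset: LeafDataset,
    config: TrainConfig,
    log_path: Optional[Path] = None,
) -> List[EpochStats]:
    """Run the full schedule: warm-up epochs first, then augmented epochs.

    Independent generator streams (spawned from ``config.seed``) drive
    shuffling and augmentation, so the shuffle sequence is identical
    whether or not augmentation is active.
    """
    root = np.random.SeedSequence(config.seed)
    seq_shuffle, seq_augment = root.spawn(2)
    rng_shuffle = np.random.default_rng(seq_shuffle)
    rng_augment = np.random.default_rng(seq_augment)
    history: List[EpochStats] = []
    writer = None
    log_file = None
    if log_path is not None:
        log_file = open(log_path, "w", newline="")
        writer = csv.writer(log_file)
        writer.writerow(["epoch", "mean_loss", "samples_seen", "augmented", "mean_lambda_max"])
    try:
        for epoch in range(config.epochs):
            apply_aug = (
                config.augmentation != "none" and epoch >= config.cam_warmup_epochs
            )
            stats = train_epoch(adapter, dataset, config, rng_shuffle, rng_augment, apply_aug)
            stats.epoch = epoch
            history.append(stats)
            if writer is not None:
                writer.writerow([stats.epoch, f"{stats.mean_loss:.10f}", stats.samples_seen,
                                 stats.augmented,
                                 "" if stats.mean_lambda_max is None else f"{stats.mean_lambda_max:.6f}"])
    finally:
        if log_file is not None:
            log_file.close()
    return history


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 plus macro averages and accuracy."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float

    def as_dict(self) -> Dict:
        return {
            "per_class": [
                {"class": k, "precision": float(p), "recall": float(r), "f1": float(f)}
                for k, (p, r, f) in enumerate(zip(self.precision, self.recall, self.f1))
            ],
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
        }


def evaluate(adapter, dataset: LeafDataset) -> np.ndarray:
    """Confusion matrix (rows = true class, cols = predicted class)."""
    if len(dataset) == 0:
        raise ValidationError("cannot evaluate an empty dataset")
    K = dataset.num_classes
    counts = np.zeros((K, K), dtype=int)
    for sample in dataset.samples:
        pred = int(np.argmax(adapter.predict_logits(sample)))
        counts[sample.label, pred] += 1
    return counts


def confusion_matrix(true: Sequence[int], pred: Sequence[int], num_classes: int) -> np.ndarray:
    counts = np.zeros((num_classes, num_classes), dtype=int)
    for t, p in zip(true, pred):
        counts[int(t), int(p)] += 1
    return counts


def metrics_from_confusion(cm: np.ndarray) -> ClassMetrics:
    """Precision, recall, F1 (per class and macro) and overall accuracy.

    A class absent from the predictions (or the ground truth) gets
    precision (recall) zero rather than NaN.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValidationError(f"confusion matrix must be square, got {cm.shape}")
    if cm.sum() == 0:
        raise ValidationError("confusion matrix is empty")
    if np.any(cm < 0):
        raise ValidationError("confusion matrix counts must be non-negative")
    tp = np.diag(cm).astype(float)
    colsum = cm.sum(axis=0).astype(float)
    rowsum = cm.sum(axis=1).astype(float)
    precision = np.divide(tp, colsum, out=np.zeros_like(tp), where=colsum > 0)
    recall = np.divide(tp, rowsum, out=np.zeros_like(tp), where=rowsum > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(tp), where=pr > 0)
    return ClassMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(tp.sum() / cm.sum()),
    )
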