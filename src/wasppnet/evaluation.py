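"""Leave-One-Subject-Out (LOSO) training and evaluation.

LOSO holds out every sample of one subject per fold and trains on the
remaining subjects, so reported performance is never inflated by subject
identity leakage — the standard protocol in micro-expression work, where
per-subject appearance is a strong confound.  Metrics are computed on the
predictions pooled across all folds (per-fold reports are kept as well).

Training uses Adam on categorical cross-entropy.  Each fold trains a
freshly initialized model with a fold-specific seed (global seed + fold
index) and normalizes inputs per channel with statistics estimated from
that fold's training portion only.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import nn
from .architectures import ArchitectureSpec, Network, build_variant, \
    count_parameters
from .metrics import MetricsReport, multiclass_report
from .synthetic_data import FlowDataset

__all__ = ["TrainConfig", "FoldResult", "LOSOResult", "TrainingDiverged",
           "loso_folds", "train_fold", "evaluate_loso", "compare_variants"]


class TrainingDiverged(RuntimeError):
    pass


#: Channel-width multiplier for desk-scale (single-CPU) experiments; the
#: full-scale networks use width 1.
DESK_SCALE_WIDTH = 1 / 32


def desk_scale_train_config(seed: int = 0, epochs: int = 8) -> "TrainConfig":
    """Training settings sized for desk-scale runs of the width-scaled
    networks: a larger learning rate and smaller batches suit the much
    smaller parameter count, and the synthetic task converges within a
    few epochs."""
    return TrainConfig(learning_rate=1e-3, batch_size=16, epochs=epochs,
                       seed=seed)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    loss: str = "categorical_cross_entropy"

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy is supported")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training hyperparameters")


@dataclasses.dataclass
class FoldResult:
    held_out_subject: str
    sample_ids: list[str]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    loss_trace: list[float]


@dataclasses.dataclass
class LOSOResult:
    folds: list[FoldResult]
    pooled_report: MetricsReport
    per_fold_reports: list[MetricsReport]

    def predictions_frame(self) -> pd.DataFrame:
        rows = []
        for fold in self.folds:
            for sid, t, p in zip(fold.sample_ids, fold.true_labels,
                                 fold.predicted_labels):
                rows.append({"subject": fold.held_out_subject,
                             "sample_id": sid, "true": t, "predicted": p})
        return pd.DataFrame(rows)

    def loss_traces_frame(self) -> pd.DataFrame:
        rows = []
        for fold in self.folds:
            for epoch, loss in enumerate(fold.loss_trace, start=1):
                rows.append({"subject": fold.held_out_subject,
                             "epoch": epoch, "loss": loss})
        return pd.DataFrame(rows)


def loso_folds(dataset: FlowDataset) -> list[tuple[str, np.ndarray,
                                                   np.ndarray]]:
    """One (held_out_subject, train_idx, test_idx) triple per subject,
    in lexicographic subject order."""
    subjects = sorted(set(dataset.subjects.tolist()))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    folds = []
    for subject in subjects:
        test = np.flatnonzero(dataset.subjects == subject)
        train = np.flatnonzero(dataset.subjects != subject)
        folds.append((subject, train, test))
    return folds


def train_fold(model: Network, images: np.ndarray, label_idx: np.ndarray,
               config: TrainConfig) -> list[float]:
    """Optimize ``model`` in place; returns the per-epoch mean loss
    trace.  Fully seed-determined (shuffling included)."""
    n_classes = model.spec.n_classes
    present = np.bincount(label_idx, minlength=n_classes)
    if np.any(present == 0):
        warnings.warn(
            f"training fold is missing {int(np.sum(present == 0))} "
            "class(es); the model cannot learn to predict them",
            stacklevel=2)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model, lr=config.learning_rate)
    n = images.shape[0]
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = model.forward_logits(images[batch], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, label_idx[batch])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss {loss} at epoch {len(trace) + 1}")
            model.backward_from_logits(grad)
            opt.step()
            epoch_loss += loss * batch.size
        trace.append(epoch_loss / n)
    return trace


def _channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = images.mean(axis=(0, 2, 3), keepdims=True)
    std = images.std(axis=(0, 2, 3), keepdims=True)
    std[std < 1e-6] = 1.0
    return mean.astype(np.float32), std.astype(np.float32)


def evaluate_loso(spec: ArchitectureSpec, dataset: FlowDataset,
                  config: TrainConfig) -> LOSOResult:
    """Run the full LOSO protocol for one architecture.

    A fresh model is initialized per fold (seed = global seed + fold
    index); all held-out predictions are pooled before scoring.
    """
    classes = sorted(set(dataset.labels.tolist()))
    if len(classes) > spec.n_classes:
        raise ValueError(
            f"dataset has {len(classes)} classes, spec allows "
            f"{spec.n_classes}")
    class_index = {c: i for i, c in enumerate(classes)}
    label_idx = np.array([class_index[l] for l in dataset.labels])

    folds = loso_folds(dataset)
    fold_results = []
    per_fold_reports = []
    for fold_i, (subject, train_idx, test_idx) in enumerate(folds):
        fold_seed = config.seed + fold_i
        model = build_variant(spec, seed=fold_seed)
        mean, std = _channel_stats(dataset.images[train_idx])
        train_images = (dataset.images[train_idx] - mean) / std
        test_images = (dataset.images[test_idx] - mean) / std
        fold_config = dataclasses.replace(config, seed=fold_seed)
        trace = train_fold(model, train_images, label_idx[train_idx],
                           fold_config)
        pred_idx = model.predict(test_images)
        predicted = np.array([classes[i] for i in pred_idx])
        true = dataset.labels[test_idx]
        fold_results.append(FoldResult(
            held_out_subject=subject,
            sample_ids=dataset.manifest["sample_id"].iloc[test_idx].tolist(),
            true_labels=true, predicted_labels=predicted, loss_trace=trace))
        per_fold_reports.append(multiclass_report(true, predicted))
    pooled_true = np.concatenate([f.true_labels for f in fold_results])
    pooled_pred = np.concatenate([f.predicted_labels for f in fold_results])
    return LOSOResult(fold_results,
                      multiclass_report(pooled_true, pooled_pred),
                      per_fold_reports)


def compare_variants(dataset: FlowDataset, specs: list[ArchitectureSpec],
                     config: TrainConfig) -> pd.DataFrame:
    """One LOSO run per spec; returns a table with pooled accuracy,
    macro/micro F1 and the parameter count, sorted by accuracy (stable,
    ties broken by spec name)."""
    if not specs:
        raise ValueError("at least one spec required")
    rows = []
    for spec in specs:
        result = evaluate_loso(spec, dataset, config)
        report = result.pooled_report
        rows.append({
            "name": spec.name or spec.module_kind,
            "accuracy": report.accuracy,
            "macro_f1": report.macro_f1,
            "micro_f1": report.micro_f1,
            "n_parameters": count_parameters(build_variant(spec,
                                                           seed=config.seed)),
        })
    frame = pd.DataFrame(rows).sort_values(
        ["accuracy", "name"], ascending=[False, True], kind="stable")
    return frame.reset_index(drop=True)
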