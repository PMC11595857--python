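"""Training protocol: loss, Adam optimizer, plateau LR schedule, early
stopping, seeding and per-epoch history logging.

The shipped defaults are the protocol used for the published experiments:
Adam with learning rate 0.001 and weight decay 1e-4, batch size 128, at most
200 epochs, a reduce-on-plateau schedule in minimize mode with factor 0.5,
early stopping after 50 consecutive epochs without an accuracy improvement,
and the global random seed fixed to 2022. The plateau schedule monitors
validation loss (patience 10); early stopping monitors validation accuracy
with a strict ``>`` improvement test.
"""

from __future__ import annotations

import csv
import io
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .backbone import ArchitectureSpec, build_esa_resnet34


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def set_global_seed(seed: int) -> None:
    """Seed every stochastic component in the package.

    Weight initialisation, shuffling, dropout and augmentation all draw from
    one generator, so two runs with the same seed and configuration are
    bit-identical.
    """
    nn.set_rng(int(seed))
    random.seed(int(seed))
    np.random.seed(int(seed) % 2**32)


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class ArrayDataset:
    """An in-memory labeled image set: images N×3×H×W float32, labels N."""

    images: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError(f"images must be N×C×H×W, got shape {self.images.shape}")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels differ in length")

    def __len__(self):
        return len(self.labels)


# ---------------------------------------------------------------------------
# Configuration and history
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    weight_decay: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 200
    early_stop_patience: int = 50
    lr_reduce_factor: float = 0.5
    scheduler_patience: int = 10
    scheduler_monitor: str = "validation_loss"
    early_stop_monitor: str = "validation_accuracy"
    seed: int = 2022
    class_weights: list[float] | None = None

    def validate(self) -> None:
        if not 0.0 < self.lr_reduce_factor < 1.0:
            raise ValueError("lr_reduce_factor must be in (0, 1), got "
                             f"{self.lr_reduce_factor}")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be < max_epochs")
        if min(self.learning_rate, self.weight_decay) < 0 or self.learning_rate == 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        for mon in (self.scheduler_monitor, self.early_stop_monitor):
            if mon not in ("validation_loss", "validation_accuracy"):
                raise ValueError(f"unknown monitored quantity {mon!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    validation_loss: float
    validation_accuracy: float
    learning_rate: float


@dataclass
class TrainingHistory:
    """Per-epoch training log plus the stopping outcome."""

    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0
    stop_reason: str = ""

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["epoch", "train_loss", "train_accuracy",
                    "validation_loss", "validation_accuracy", "learning_rate"])
        for r in self.records:
            w.writerow([r.epoch, f"{r.train_loss:.6f}", f"{r.train_accuracy:.6f}",
                        f"{r.validation_loss:.6f}", f"{r.validation_accuracy:.6f}",
                        f"{r.learning_rate:.8f}"])
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps({
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
            "stop_reason": self.stop_reason,
            "records": [asdict(r) for r in self.records],
        }, indent=2)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy on predicted class *probabilities*.

    ``L = −(1/N) Σ_i Σ_c y_ic log p_ic`` with one-hot indicators y. Each row
    of ``probabilities`` must sum to 1. During training the package never
    evaluates this on probabilities — the equivalent log-sum-exp form on raw
    scores (:func:`esanet.nn.softmax_cross_entropy`) is used instead, which
    is immune to ``p = 0`` at the true class.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.ndim != 2:
        raise ValueError(f"probabilities must be N×M, got shape {p.shape}")
    if np.any((y < 0) | (y >= p.shape[1])):
        raise ValueError(f"labels out of range [0, {p.shape[1]})")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("each probability row must sum to 1")
    picked = p[np.arange(len(y)), y]
    with np.errstate(divide="ignore"):
        return float(-np.mean(np.log(picked)))


# ---------------------------------------------------------------------------
# Schedulers (standalone so their exact halting behaviour is testable)
# ---------------------------------------------------------------------------


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without strict improvement."""

    def __init__(self, patience: int, mode: str = "max"):
        self.patience = patience
        self.mode = mode
        self.best = -np.inf if mode == "max" else np.inf
        self.best_epoch = 0
        self.bad_epochs = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record this epoch's monitored value; return True to halt now."""
        improved = value > self.best if self.mode == "max" else value < self.best
        if improved:
            self.best, self.best_epoch, self.bad_epochs = value, epoch, 0
        else:
            self.bad_epochs += 1
        return self.patience > 0 and self.bad_epochs >= self.patience


class PlateauScheduler:
    """Multiply the learning rate by ``factor`` when the monitored quantity
    stops improving (minimize mode), mirroring the standard reduce-on-plateau
    rule: reduce once more than ``patience`` consecutive bad epochs accrue."""

    def __init__(self, optimizer: nn.Adam, factor: float = 0.5,
                 patience: int = 10, mode: str = "min"):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.mode = mode
        self.best = np.inf if mode == "min" else -np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> bool:
        improved = value < self.best if self.mode == "min" else value > self.best
        if improved:
            self.best, self.bad_epochs = value, 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.optimizer.lr *= self.factor
            self.bad_epochs = 0
            return True
        return False


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the partial history."""

    def __init__(self, message: str, history: TrainingHistory):
        super().__init__(message)
        self.history = history


def evaluate(model: nn.Module, dataset: ArrayDataset, batch_size: int = 128):
    """Mean loss, accuracy and predicted labels on ``dataset`` (eval mode)."""
    model.eval()
    losses, preds = [], []
    for start in range(0, len(dataset), batch_size):
        xb = dataset.images[start:start + batch_size]
        yb = dataset.labels[start:start + batch_size]
        logits = model(xb)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        preds.append(logits.argmax(axis=1))
    preds = np.concatenate(preds)
    acc = float((preds == dataset.labels).mean())
    return float(np.sum(losses) / len(dataset)), acc, preds


def train_model(model: nn.Module, train_set: ArrayDataset,
                validation_set: ArrayDataset, config: TrainingConfig,
                verbose: bool = False):
    """Run the full protocol; return ``(best_state, history)``.

    The returned state is the parameter snapshot from the epoch with the
    highest validation accuracy (not the final epoch). The model is left
    loaded with that best state.
    """
    config.validate()
    if len(train_set) == 0 or len(validation_set) == 0:
        raise ValueError("datasets must be non-empty")
    for ds in (train_set, validation_set):
        if np.any(ds.labels < 0):
            raise ValueError("negative class labels")

    weights = None
    if config.class_weights is not None:
        weights = np.asarray(config.class_weights, dtype=np.float32)

    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    scheduler = PlateauScheduler(opt, factor=config.lr_reduce_factor,
                                 patience=config.scheduler_patience)
    stopper = EarlyStopper(config.early_stop_patience)
    history = TrainingHistory()
    best_state = nn.clone_state(model.state_dict())
    best_epoch = 0
    n = len(train_set)
    stop_reason = "max_epochs"

    for epoch in range(1, config.max_epochs + 1):
        model.train()
        perm = nn.get_rng().permutation(n)
        tot_loss, tot_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = train_set.images[idx], train_set.labels[idx]
            logits = model(xb)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if weights is not None:
                wb = weights[yb]
                per = -np.log(np.clip(nn.softmax(logits)[np.arange(len(yb)), yb],
                                      1e-12, None))
                loss = float(np.mean(wb * per))
                dlogits = dlogits * wb[:, None] * (len(yb) / max(wb.sum(), 1e-12))
            if not np.isfinite(loss):
                history.stopped_epoch = epoch
                history.stop_reason = "diverged"
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}", history)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            tot_loss += loss * len(yb)
            tot_correct += int((logits.argmax(axis=1) == yb).sum())
        train_loss = tot_loss / n
        train_acc = tot_correct / n

        val_loss, val_acc, _ = evaluate(model, validation_set, config.batch_size)
        monitored_sched = (val_loss if config.scheduler_monitor == "validation_loss"
                           else -val_acc)
        scheduler.step(monitored_sched)
        history.records.append(EpochRecord(
            epoch, train_loss, train_acc, val_loss, val_acc, opt.lr))
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}/{train_acc:.3f}  "
                  f"val {val_loss:.4f}/{val_acc:.3f}  lr {opt.lr:.2e}")

        monitored_stop = (val_acc if config.early_stop_monitor ==
                          "validation_accuracy" else -val_loss)
        improved = monitored_stop > stopper.best
        if stopper.update(epoch, monitored_stop):
            stop_reason = "early_stop"
            history.stopped_epoch = epoch
            break
        if improved:
            best_state = nn.clone_state(model.state_dict())
            best_epoch = epoch
    else:
        history.stopped_epoch = config.max_epochs
    history.stop_reason = stop_reason
    history.best_epoch = best_epoch
    model.load_state_dict(best_state)
    return best_state, history


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: nn.Module,
                    spec: ArchitectureSpec | None = None) -> None:
    """Write the model state as ``.npz`` with a JSON architecture sidecar,
    so every checkpoint is self-describing."""
    path = Path(path).with_suffix(".npz")
    with open(path, "wb") as fh:
        np.savez(fh, **model.state_dict())
    spec = spec or getattr(model, "spec", None)
    if spec is not None:
        path.with_suffix(".json").write_text(
            json.dumps(spec.to_dict(), indent=2))


def load_checkpoint(path):
    """Rebuild the model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path).with_suffix(".npz")
    spec_path = path.with_suffix(".json")
    if not spec_path.exists():
        raise FileNotFoundError(f"architecture sidecar {spec_path} not found")
    spec = ArchitectureSpec.from_dict(json.loads(spec_path.read_text()))
    model = build_esa_resnet34(spec)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, spec
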