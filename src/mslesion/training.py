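"""Cross-validated training protocol.

Two strategies mirror the study design: ``continued`` keeps a single model
instance and trains it further on every successive fold's training split
(the better-performing protocol), while ``fresh_per_fold`` re-initializes
the network for each fold.  Validation splits are monitored only — no early
stopping or selection happens during a run.  Hyperparameters are explored
with a random grid search over batch sizes 2-10 and log-uniform learning
rates in [1e-6, 1e-5].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .dataset import (AugmentationPolicy, FoldPlan, LabeledDataset,
                      compute_class_weights, random_transform, rotate_flip)
from .models import ArchitectureSpec, TrainableModel, build_model

PAPER_BATCH_RANGE = (2, 10)
PAPER_LR_RANGE = (1e-6, 1e-5)


class TrainingDivergence(RuntimeError):
    def __init__(self, fold: int, epoch: int):
        super().__init__(f"non-finite loss at fold {fold}, epoch {epoch}")
        self.fold, self.epoch = fold, epoch


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-5
    epochs_per_fold: int = 100
    strategy: str = "continued"
    optimizer: str = "adam"
    seed: int = 0
    augmentation: AugmentationPolicy | None = None
    materialize_augmentation: bool = False
    use_class_weights: bool = False

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs_per_fold < 1:
            raise ValueError("batch_size and epochs_per_fold must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.strategy not in ("continued", "fresh_per_fold"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass(frozen=True)
class EpochRecord:
    fold: int
    epoch: int
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float


@dataclass
class TrainingTrace:
    records: list[EpochRecord] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @property
    def final_validation_accuracy(self) -> float:
        return self.records[-1].val_accuracy

    def validation_accuracies(self) -> list[float]:
        return [r.val_accuracy for r in self.records]


def _onehot(indices: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(indices), n_classes))
    out[np.arange(len(indices)), indices] = 1.0
    return out


def _evaluate(network: nn.Network, x: np.ndarray, t: np.ndarray,
              class_w: np.ndarray) -> tuple[float, float]:
    s = network.predict_proba(x)
    w = class_w[t.argmax(axis=1)]
    per = -(t * np.log(np.maximum(s, 1e-7))).sum(axis=1)
    loss = float(np.mean(w * per))
    acc = float(np.mean(s.argmax(axis=1) == t.argmax(axis=1)))
    return loss, acc


def train_cross_validated(spec: ArchitectureSpec, data: LabeledDataset,
                          plan: FoldPlan, config: TrainConfig
                          ) -> tuple[TrainableModel, TrainingTrace]:
    """Run the full cross-validation protocol and return the final model
    plus the per-(fold, epoch) accuracy/loss trace."""
    n_classes = len(data.class_names)
    x_all = data.stack()
    if len(spec.input_shape) == 4:
        x_all = x_all[..., None]
    y_all = _onehot(data.label_indices, n_classes)
    class_w = (compute_class_weights(data).as_array(data.class_names)
               if config.use_class_weights else np.ones(n_classes))

    ss = np.random.SeedSequence(config.seed)
    init_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    rng = np.random.default_rng(ss.spawn(1)[0])

    model = build_model(spec, seed=init_seed)
    optimizer = nn.Adam(model.network.params, lr=config.learning_rate)
    trace = TrainingTrace()

    for fold_i, (train_idx, val_idx) in enumerate(plan.folds):
        if config.strategy == "fresh_per_fold" and fold_i > 0:
            model = build_model(spec, seed=init_seed + fold_i)
            optimizer = nn.Adam(model.network.params, lr=config.learning_rate)
        xt, yt = x_all[train_idx], y_all[train_idx]
        xv, yv = x_all[val_idx], y_all[val_idx]
        augmenting = (config.augmentation is not None
                      and config.augmentation.factor > 1)
        if augmenting and config.materialize_augmentation:
            # dataset-level multiplication: factor-1 fixed transformed copies
            # per training cube, so every epoch sees the enlarged set
            xt, yt = _materialize_augmentation(
                xt, yt, config.augmentation, rng, len(spec.input_shape))
        for epoch in range(config.epochs_per_fold):
            order = rng.permutation(len(xt))
            losses, hits, seen = [], 0, 0
            for start in range(0, len(order), config.batch_size):
                sel = order[start:start + config.batch_size]
                xb, yb = xt[sel], yt[sel]
                if augmenting and not config.materialize_augmentation:
                    xb = _augment_batch(xb, config.augmentation, rng,
                                        cube_ndim=len(spec.input_shape))
                logits = model.network.forward(xb, train=True, rng=rng)
                w = class_w[yb.argmax(axis=1)]
                loss, dlogits = nn.cross_entropy_with_logits(logits, yb, w)
                if not np.isfinite(loss):
                    raise TrainingDivergence(fold_i, epoch)
                model.network.backward(dlogits)
                optimizer.step(model.network.grads)
                losses.append(loss * len(sel))
                hits += int(np.sum(logits.argmax(axis=1) == yb.argmax(axis=1)))
                seen += len(sel)
            val_loss, val_acc = _evaluate(model.network, xv, yv, class_w)
            trace.records.append(EpochRecord(
                fold=fold_i, epoch=epoch,
                train_loss=float(np.sum(losses) / seen),
                train_accuracy=hits / seen,
                val_loss=val_loss, val_accuracy=val_acc))
    return model, trace


def _materialize_augmentation(xt: np.ndarray, yt: np.ndarray,
                              policy: AugmentationPolicy,
                              rng: np.random.Generator,
                              cube_ndim: int) -> tuple[np.ndarray, np.ndarray]:
    parts_x, parts_y = [xt], [yt]
    for _ in range(policy.factor - 1):
        parts_x.append(_augment_batch(xt, policy, rng, cube_ndim))
        parts_y.append(yt)
    return np.concatenate(parts_x), np.concatenate(parts_y)


def _augment_batch(xb: np.ndarray, policy: AugmentationPolicy,
                   rng: np.random.Generator, cube_ndim: int) -> np.ndarray:
    """On-the-fly geometric augmentation, one random transform per cube."""
    out = np.empty_like(xb)
    for i in range(len(xb)):
        cube = xb[i, ..., 0] if cube_ndim == 4 else xb[i]
        angle, fh, fv = random_transform(policy, rng)
        aug = rotate_flip(cube, angle, fh, fv, policy.fill)
        out[i] = aug[..., None] if cube_ndim == 4 else aug
    return out


def random_grid_search(trials: int,
                       batch_range: tuple[int, int] = PAPER_BATCH_RANGE,
                       lr_range: tuple[float, float] = PAPER_LR_RANGE,
                       seed: int = 0,
                       base: TrainConfig | None = None) -> list[TrainConfig]:
    """Sample distinct (batch size, learning rate) configs: batch uniform on
    the integer grid, learning rate log-uniform over its range."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = base or TrainConfig()
    seen: set[tuple[int, float]] = set()
    configs: list[TrainConfig] = []
    attempts = 0
    while len(configs) < trials and attempts < 1000 * trials:
        attempts += 1
        batch = int(rng.integers(batch_range[0], batch_range[1] + 1))
        lr = float(np.exp(rng.uniform(np.log(lr_range[0]), np.log(lr_range[1]))))
        key = (batch, round(lr, 12))
        if key in seen:
            continue
        seen.add(key)
        configs.append(replace(base, batch_size=batch, learning_rate=lr))
    return configs
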