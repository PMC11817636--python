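"""Labeled cube collections: balancing, class weights, stratified folds,
and geometric augmentation.

The study protocol this module encodes: downsample the imbalanced cohort to
the minority class count (70/70/70), hold out a stratified 20% test set,
5-fold-stratify the remaining pool, and augment training cubes with random
rotations and flips applied identically to every band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import rotate as nd_rotate
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.class_weight import compute_class_weight

from .calibration import ReflectanceCube
from .phantom import CLASS_NAMES


@dataclass
class LabeledDataset:
    """Ordered collection of labeled reflectance cubes."""

    cubes: list[ReflectanceCube]
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        for cube in self.cubes:
            if cube.label not in self.class_names:
                raise ValueError(f"cube label {cube.label!r} not in class_names")

    def __len__(self) -> int:
        return len(self.cubes)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cubes])

    @property
    def label_indices(self) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(self.class_names)}
        return np.array([lookup[c.label] for c in self.cubes])

    @property
    def class_counts(self) -> dict[str, int]:
        labels = self.labels
        return {name: int(np.sum(labels == name)) for name in self.class_names}

    def stack(self) -> np.ndarray:
        """(N, H, W, B) value array."""
        return np.stack([c.values for c in self.cubes])

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.cubes[i] for i in indices], self.class_names)


@dataclass(frozen=True)
class ClassWeights:
    """Balanced-scheme loss weights: w_i = m / (C * n_i)."""

    weights: dict[str, float]

    def as_array(self, class_names) -> np.ndarray:
        return np.array([self.weights[name] for name in class_names])


@dataclass
class FoldPlan:
    """Held-out test indices plus k (train, validation) partitions of the pool."""

    test_indices: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    test_fraction: float

    @property
    def fold_count(self) -> int:
        return len(self.folds)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "test_indices": self.test_indices.tolist(),
            "folds": [{"train": tr.tolist(), "validation": va.tolist()}
                      for tr, va in self.folds],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        data = json.loads(Path(path).read_text())
        return cls(
            test_indices=np.array(data["test_indices"], dtype=int),
            folds=[(np.array(f["train"], dtype=int), np.array(f["validation"], dtype=int))
                   for f in data["folds"]],
            seed=data["seed"], test_fraction=data["test_fraction"])


@dataclass(frozen=True)
class AugmentationPolicy:
    """Random rotation (uniform angle) and 50/50 horizontal/vertical flips,
    applied identically to every band of a cube; reflect fill at borders."""

    rotation: bool = True
    flips: bool = True
    factor: int = 50
    fill: str = "reflect"

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("augmentation factor must be >= 1")


def balance_downsample(data: LabeledDataset,
                       rng: np.random.Generator) -> LabeledDataset:
    """Subsample every class (without replacement) to the minority count and
    shuffle the result."""
    counts = data.class_counts
    if min(counts.values()) < 1:
        raise ValueError("every class needs at least one sample")
    target = min(counts.values())
    labels = data.labels
    chosen: list[int] = []
    for name in data.class_names:
        idx = np.flatnonzero(labels == name)
        chosen.extend(rng.choice(idx, size=target, replace=False).tolist())
    order = rng.permutation(len(chosen))
    return data.subset([chosen[i] for i in order])


def compute_class_weights(data: LabeledDataset) -> ClassWeights:
    """Balanced scheme w_i = m / (C * n_i) via scikit-learn."""
    counts = data.class_counts
    if min(counts.values()) == 0:
        raise ValueError("cannot weight an empty class")
    classes = np.array(data.class_names)
    w = compute_class_weight("balanced", classes=classes, y=data.labels)
    return ClassWeights(weights={name: float(x) for name, x in zip(classes, w)})


def make_fold_plan(data: LabeledDataset, test_fraction: float = 0.2,
                   folds: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified test split, then stratified k-fold partition of the pool."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    indices = np.arange(len(data))
    labels = data.labels
    pool_idx, test_idx = train_test_split(
        indices, test_size=test_fraction, stratify=labels, random_state=seed)
    pool_labels = labels[pool_idx]
    counts = np.unique(pool_labels, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError("a class is too small for the requested fold count")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_list = [(pool_idx[tr], pool_idx[va])
                 for tr, va in skf.split(pool_idx, pool_labels)]
    return FoldPlan(test_indices=np.sort(test_idx), folds=fold_list,
                    seed=seed, test_fraction=test_fraction)


def rotate_flip(values: np.ndarray, angle: float, flip_h: bool, flip_v: bool,
                fill: str = "reflect") -> np.ndarray:
    """Apply one rigid transform to all bands of an (H, W, B) cube.

    Rotation is about the image center with bilinear interpolation and
    reflect fill, so values stay within the input range (clipped to [0, 1]
    against round-off).
    """
    out = values
    if angle != 0.0:
        out = nd_rotate(out, np.degrees(angle), axes=(0, 1), reshape=False,
                        order=1, mode=fill)
    if flip_h:
        out = out[:, ::-1, :]
    if flip_v:
        out = out[::-1, :, :]
    return np.clip(out, 0.0, 1.0)


def random_transform(policy: AugmentationPolicy, rng: np.random.Generator):
    """Draw one (angle, flip_h, flip_v) triple from the policy."""
    angle = float(rng.uniform(0.0, 2.0 * np.pi)) if policy.rotation else 0.0
    flip_h = bool(rng.random() < 0.5) if policy.flips else False
    flip_v = bool(rng.random() < 0.5) if policy.flips else False
    return angle, flip_h, flip_v


def augment(data: LabeledDataset, policy: AugmentationPolicy,
            rng: np.random.Generator) -> LabeledDataset:
    """Materialize originals plus (factor - 1) transformed copies per cube."""
    if policy.factor == 1:
        return data
    cubes: list[ReflectanceCube] = list(data.cubes)
    for cube in data.cubes:
        for copy_i in range(policy.factor - 1):
            angle, fh, fv = random_transform(policy, rng)
            cubes.append(ReflectanceCube(
                values=rotate_flip(cube.values, angle, fh, fv, policy.fill),
                wavelengths_nm=cube.wavelengths_nm, label=cube.label,
                provenance={**cube.provenance, "augmented": copy_i + 1}))
    return LabeledDataset(cubes, data.class_names)
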