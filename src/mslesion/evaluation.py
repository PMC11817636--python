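"""Confusion-matrix metrics, malignant-vs-benign collapse, and saliency maps.

Per-class metrics follow the usual one-vs-rest reading of a C x C confusion
matrix (rows = truth, columns = prediction): TP is the diagonal entry, FN the
rest of the row, FP the rest of the column, TN everything else.  Sensitivity
SE = TP/(TP+FN), specificity SP = TN/(TN+FP), precision P = TP/(TP+FP), and
F1 is the harmonic mean of SE and P.  Undefined ratios (empty denominators)
are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as sk_confusion_matrix

from .calibration import ReflectanceCube
from .models import TrainableModel

BENIGN_CLASSES = ("nevus",)
MALIGNANT_CLASSES = ("melanoma", "bcc")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                  # (C, C) ints, rows = truth
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C x C")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_counts(self, class_name: str) -> dict[str, int]:
        i = self.class_names.index(class_name)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = int(self.counts.sum() - tp - fn - fp)
        return {"tp": tp, "fn": fn, "fp": fp, "tn": tn}

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.counts, index=list(self.class_names),
                     columns=list(self.class_names)).to_csv(path)
        return path


@dataclass
class ClassMetrics:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    degenerate: bool = False


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    top1_accuracy: float
    binary_collapse: dict[str, ClassMetrics] | None = None
    binary_accuracy: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _cm(d):
            return {name: vars(m) for name, m in d.items()}
        out = {"top1_accuracy": self.top1_accuracy,
               "per_class": _cm(self.per_class),
               "provenance": self.provenance}
        if self.binary_collapse is not None:
            out["binary_collapse"] = _cm(self.binary_collapse)
            out["binary_accuracy"] = self.binary_accuracy
        return out

    def to_table(self) -> pd.DataFrame:
        """Report-style table rounded to 2 decimals."""
        rows = []
        for name, m in self.per_class.items():
            rows.append({"class": name, "SE": m.sensitivity, "SP": m.specificity,
                         "P": m.precision, "F1": m.f1})
        if self.binary_collapse is not None:
            m = self.binary_collapse["malignant"]
            rows.append({"class": "malignant_vs_benign", "SE": m.sensitivity,
                         "SP": m.specificity, "P": m.precision, "F1": m.f1})
        df = pd.DataFrame(rows).set_index("class")
        return df.round(2)


@dataclass
class SaliencyMap:
    values: np.ndarray                  # (H, W) in [0, 1]
    source_id: str | None
    target_class: str


def confusion_matrix(truth, predicted, class_names) -> ConfusionMatrix:
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    for lab in (*truth, *predicted):
        if lab not in class_names:
            raise ValueError(f"unknown label {lab!r}")
    counts = sk_confusion_matrix(truth, predicted, labels=list(class_names))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def f1_score(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision (0 when both vanish)."""
    return _safe_div(2.0 * sensitivity * precision, sensitivity + precision)[0]


def metrics_from_cm(cm: ConfusionMatrix,
                    collapse: bool = True) -> MetricsReport:
    """Per-class SE/SP/P/F1, top-1 accuracy, and (optionally) the
    malignant-vs-benign collapse of a nevus/melanoma/bcc matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if any(cm.counts[i].sum() == 0 for i in range(len(cm.class_names))):
        raise ValueError("every class needs at least one true sample")
    per_class = {}
    for name in cm.class_names:
        c = cm.per_class_counts(name)
        se, d1 = _safe_div(c["tp"], c["tp"] + c["fn"])
        sp, d2 = _safe_div(c["tn"], c["tn"] + c["fp"])
        p, d3 = _safe_div(c["tp"], c["tp"] + c["fp"])
        f1, d4 = _safe_div(2 * se * p, se + p)
        per_class[name] = ClassMetrics(sensitivity=se, specificity=sp,
                                       precision=p, f1=f1,
                                       degenerate=d1 or d2 or d3 or d4)
    report = MetricsReport(
        per_class=per_class,
        top1_accuracy=float(np.trace(cm.counts) / cm.total))
    can_collapse = all(c in cm.class_names
                       for c in (*BENIGN_CLASSES, *MALIGNANT_CLASSES))
    if collapse and can_collapse:
        bcm = collapse_malignant(cm)
        binary = metrics_from_cm(bcm, collapse=False)
        report.binary_collapse = binary.per_class
        report.binary_accuracy = binary.top1_accuracy
    return report


def collapse_malignant(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Merge melanoma + bcc into 'malignant' against benign nevi (2 x 2)."""
    for cls in (*BENIGN_CLASSES, *MALIGNANT_CLASSES):
        if cls not in cm.class_names:
            raise ValueError(f"class {cls!r} missing from matrix")
    groups = {"benign": [cm.class_names.index(c) for c in BENIGN_CLASSES],
              "malignant": [cm.class_names.index(c) for c in MALIGNANT_CLASSES]}
    out = np.zeros((2, 2), dtype=int)
    names = ("benign", "malignant")
    for r, rname in enumerate(names):
        for c, cname in enumerate(names):
            out[r, c] = cm.counts[np.ix_(groups[rname], groups[cname])].sum()
    return ConfusionMatrix(counts=out, class_names=names)


def evaluate_predictions(model: TrainableModel, data, indices=None) -> MetricsReport:
    """Predict a labeled dataset (or a subset) and compute the full report."""
    subset = data if indices is None else data.subset(indices)
    x = subset.stack()
    pred_idx = model.predict_indices(x)
    predicted = [subset.class_names[i] for i in pred_idx]
    cm = confusion_matrix(subset.labels, predicted, subset.class_names)
    report = metrics_from_cm(cm)
    report.provenance = {"n": len(subset), "architecture": model.spec.name}
    return report


def saliency_map(model: TrainableModel, cube: ReflectanceCube) -> SaliencyMap:
    """Input-gradient saliency: |d top-class score / d input|, maximum over
    the band axis, min-max normalized to [0, 1] (left all-zero when the
    gradient vanishes everywhere)."""
    x = cube.values[None]
    if len(model.spec.input_shape) == 4:
        x = x[..., None]
    top = int(model.predict_proba(cube.values).argmax())
    grad = model.network.input_gradient(x, top)
    if not np.isfinite(grad).all():
        raise FloatingPointError("non-finite gradients in saliency computation")
    mag = np.abs(grad[0])
    while mag.ndim > 2:                 # reduce band (and channel) axes
        mag = mag.max(axis=-1)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return SaliencyMap(values=mag,
                       source_id=str(cube.provenance.get("index")),
                       target_class=model.spec.name and
                       _class_name(model, top))


def _class_name(model: TrainableModel, index: int) -> str:
    from .phantom import CLASS_NAMES
    names = CLASS_NAMES if model.spec.class_count == len(CLASS_NAMES) else \
        tuple(str(i) for i in range(model.spec.class_count))
    return names[index]
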