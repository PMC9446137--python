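"""Agreement between two label maps: confusion matrix, per-class
precision / recall / F-score, difference images, and pooled vs macro
aggregation over a set of image pairs.

Precision for class c is the fraction of pixels predicted c that truly are
c (low false-positive rate); recall is the fraction of truly-c pixels that
were predicted c; the F-score is their harmonic mean.  Because reports
aggregated over many images can follow either rule — metrics of the summed
confusion matrix ("pooled") or per-image metrics averaged ("macro") — both
are always emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DomainError
from .labeling import LabelMap, TissuePalette

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "fscore",
    "difference_map",
    "metrics_report",
    "write_metrics_csv",
    "save_difference_png",
]


@dataclass(frozen=True)
class ClassMetrics:
    class_id: int
    precision: float
    recall: float
    fscore: float


@dataclass
class ConfusionMatrix:
    """counts[t, p] = pixels with truth class classes[t] predicted classes[p]."""

    classes: list[int]
    counts: np.ndarray
    ignored: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise DomainError(f"counts must be {c}x{c}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise DomainError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise DomainError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(
            self.classes, self.counts + other.counts, self.ignored + other.ignored
        )


def fscore(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_matrix(
    pred: LabelMap,
    truth: LabelMap,
    palette: TissuePalette,
    ignore_unlabeled: bool = True,
) -> ConfusionMatrix:
    """Tally pixel pairs over the palette classes.

    With ``ignore_unlabeled`` (default), pixels where either map is 0 are
    excluded and counted in ``ignored``.
    """
    if pred.shape != truth.shape:
        raise DomainError(
            f"dimension mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    ids = palette.ids
    c = len(ids)
    t = truth.labels.ravel()
    p = pred.labels.ravel()
    if ignore_unlabeled:
        keep = (t > 0) & (p > 0)
    else:
        keep = np.ones(t.shape, dtype=bool)
        if (t == 0).any() or (p == 0).any():
            raise DomainError(
                "maps contain unlabeled pixels; use ignore_unlabeled=True"
            )
    t, p = t[keep], p[keep]
    if (t > c).any() or (p > c).any():
        raise DomainError("label maps contain ids outside the palette")
    counts = np.bincount((t - 1) * c + (p - 1), minlength=c * c).reshape(c, c)
    return ConfusionMatrix(ids, counts, ignored=int((~keep).sum()))


def class_metrics(cm: ConfusionMatrix) -> list[ClassMetrics]:
    """Per-class precision/recall/F from a confusion matrix.

    A zero denominator (class absent from truth or prediction) yields 0.0
    with a warning.
    """
    out = []
    col = cm.counts.sum(axis=0)
    row = cm.counts.sum(axis=1)
    for i, cid in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        if col[i] == 0 or row[i] == 0:
            if col[i] == 0:
                warnings.warn(
                    f"class {cid}: no predicted pixels; precision set to 0",
                    stacklevel=2,
                )
            if row[i] == 0:
                warnings.warn(
                    f"class {cid}: no truth pixels; recall set to 0", stacklevel=2
                )
        precision = tp / col[i] if col[i] > 0 else 0.0
        recall = tp / row[i] if row[i] > 0 else 0.0
        out.append(ClassMetrics(cid, precision, recall, fscore(precision, recall)))
    return out


def difference_map(a: LabelMap, b: LabelMap) -> np.ndarray:
    """Binary H x W map: 1 where the two labelings disagree."""
    if a.shape != b.shape:
        raise DomainError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return (a.labels != b.labels).astype(np.uint8)


def save_difference_png(diff: np.ndarray, path) -> None:
    """Write a difference map as a binary (black/white) PNG."""
    Image.fromarray((diff > 0).astype(np.uint8) * 255, mode="L").save(path, "PNG")


def metrics_report(
    pairs,
    palette: TissuePalette,
    ignore_unlabeled: bool = True,
) -> pd.DataFrame:
    """Pooled and macro per-class metrics over (pred, truth) pairs.

    Pooled: confusion matrices are summed, then metrics computed once.
    Macro: metrics per pair, averaged over pairs where the class occurs in
    the truth map.  Columns: class, name, precision, recall, fscore,
    aggregation.
    """
    pairs = list(pairs)
    if not pairs:
        raise DomainError("metrics_report requires at least one (pred, truth) pair")
    cms = [confusion_matrix(p, t, palette, ignore_unlabeled) for p, t in pairs]
    pooled = cms[0]
    for cm in cms[1:]:
        pooled = pooled + cm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_pair = [class_metrics(cm) for cm in cms]
        pooled_metrics = class_metrics(pooled)

    rows = []
    for i, cid in enumerate(pooled.classes):
        m = pooled_metrics[i]
        rows.append(
            {
                "class": cid,
                "name": palette.name_of(cid),
                "precision": m.precision,
                "recall": m.recall,
                "fscore": m.fscore,
                "aggregation": "pooled",
            }
        )
    for i, cid in enumerate(pooled.classes):
        present = [
            pm[i] for cm, pm in zip(cms, per_pair) if cm.counts[i, :].sum() > 0
        ]
        if present:
            prec = float(np.mean([m.precision for m in present]))
            rec = float(np.mean([m.recall for m in present]))
            f = float(np.mean([m.fscore for m in present]))
        else:
            warnings.warn(
                f"class {cid} absent from every truth map; macro metrics set to 0",
                stacklevel=2,
            )
            prec = rec = f = 0.0
        rows.append(
            {
                "class": cid,
                "name": palette.name_of(cid),
                "precision": prec,
                "recall": rec,
                "fscore": f,
                "aggregation": "macro",
            }
        )
    return pd.DataFrame(rows)


def write_metrics_csv(report: pd.DataFrame, path) -> None:
    """Write a metrics table rounded to 4 decimals (full precision is kept
    in the DataFrame)."""
    out = report.copy()
    for col in ("precision", "recall", "fscore"):
        out[col] = out[col].round(4)
    out.to_csv(path, index=False)
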