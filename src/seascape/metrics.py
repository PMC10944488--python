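"""Classification evaluation: confusion matrices, precision/recall/F, top-k.

Definitions follow the standard one-vs-rest decomposition of a multiclass
confusion matrix:

    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F         = 2 * Recall * Precision / (Recall + Precision)
    Accuracy  = (TP + TN) / (TP + FP + FN + TN)

Top-1 accuracy is the fraction of items whose true label equals the most
probable prediction; Top-5 counts the true label anywhere in the five most
probable.  All metrics can be computed at any taxonomy level by mapping
Level-3 labels to their Level-2/Level-1 parents first.

A per-class precision with no predicted positives (TP + FP = 0) is treated
as 0 and flagged in the returned report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ProbabilityVector
from .taxonomy import SoundTaxonomy


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = items with true label i predicted as label j."""

    counts: np.ndarray
    labels: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Aggregate metrics (percent) per level, plus the averaging mode used."""

    level: int
    averaging: str
    precision_pct: float
    recall_pct: float
    f_measure_pct: float
    top1_accuracy_pct: float
    top5_accuracy_pct: float
    undefined_precision_classes: tuple[str, ...] = field(default_factory=tuple)


def _to_level(labels, taxonomy: SoundTaxonomy, level: int) -> list[str]:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if level == 3:
                out.append(lab)
            else:
                out.append(taxonomy.level_label(taxonomy.id_for_name(lab), level))
        else:
            out.append(taxonomy.level_label(int(lab), level))
    return out


def confusion(
    y_true, y_pred, taxonomy: SoundTaxonomy, level: int = 3
) -> ConfusionMatrix:
    """Confusion matrix at a level; class order follows the taxonomy."""
    if len(y_true) != len(y_pred):
        raise ValueError("label lists must have equal length")
    labels = taxonomy.level_labels(level)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(_to_level(y_true, taxonomy, level), _to_level(y_pred, taxonomy, level)):
        if t not in index or p not in index:
            raise ValueError(f"unknown label {t if t not in index else p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def precision_recall_f(
    cm: ConfusionMatrix, averaging: str = "macro"
) -> tuple[float, float, float]:
    """Aggregate (precision, recall, F) as fractions in [0, 1].

    ``macro`` is the unweighted mean of per-class one-vs-rest metrics;
    ``micro`` pools TP/FP/FN over classes.  Undefined per-class values
    (zero denominator) count as 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    fp = cm.counts.sum(axis=0) - tp
    fn = cm.counts.sum(axis=1) - tp
    if averaging == "micro":
        tp, fp, fn = tp.sum(), fp.sum(), fn.sum()
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    elif averaging == "macro":
        with np.errstate(invalid="ignore", divide="ignore"):
            per_p = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
            per_r = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
        precision, recall = float(per_p.mean()), float(per_r.mean())
    else:
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    f = 2 * recall * precision / (recall + precision) if recall + precision > 0 else 0.0
    return float(precision), float(recall), float(f)


def undefined_precision_classes(cm: ConfusionMatrix) -> tuple[str, ...]:
    """Classes with no predicted positives (precision undefined, scored 0)."""
    tp = np.diag(cm.counts)
    pred_pos = cm.counts.sum(axis=0)
    return tuple(lab for lab, n in zip(cm.labels, pred_pos) if n == 0)


def accuracy(
    y_true,
    predictions,
    taxonomy: SoundTaxonomy,
    k: int = 1,
    level: int = 3,
) -> float:
    """Top-k accuracy at a level.

    ``predictions`` may be ProbabilityVectors (top-k taken per item) or, for
    k=1 only, hard Level-3 labels.  The item scores when its true
    level-mapped label appears among the level-mapped top-k predictions.
    """
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    true_lv = _to_level(y_true, taxonomy, level)
    hits = 0
    for t, pred in zip(true_lv, predictions):
        if isinstance(pred, ProbabilityVector):
            top = {taxonomy.level_label(c, level) for c, _ in pred.topk(k)}
        else:
            if k != 1:
                raise ValueError("top-k > 1 requires probability vectors")
            top = {_to_level([pred], taxonomy, level)[0]}
        hits += t in top
    return hits / len(y_true)


def metrics_report(
    y_true,
    prob_vectors,
    taxonomy: SoundTaxonomy,
    level: int,
    averaging: str = "macro",
    include_background: bool = True,
) -> MetricsReport:
    """Full per-level report in percent, mirroring one row block of the
    evaluation table (Recall / Precision / F-measure plus Top-1/Top-5)."""
    y_pred = [pv.argmax() for pv in prob_vectors]
    if not include_background:
        bg = taxonomy.background_id
        keep = [i for i, t in enumerate(np.asarray(y_true, dtype=int)) if t != bg]
        y_true = [y_true[i] for i in keep]
        y_pred = [y_pred[i] for i in keep]
        prob_vectors = [prob_vectors[i] for i in keep]
    cm = confusion(y_true, y_pred, taxonomy, level)
    p, r, f = precision_recall_f(cm, averaging)
    return MetricsReport(
        level=level,
        averaging=averaging,
        precision_pct=round(100 * p, 1),
        recall_pct=round(100 * r, 1),
        f_measure_pct=round(100 * f, 1),
        top1_accuracy_pct=round(100 * accuracy(y_true, prob_vectors, taxonomy, 1, level), 1),
        top5_accuracy_pct=round(100 * accuracy(y_true, prob_vectors, taxonomy, 5, level), 1),
        undefined_precision_classes=undefined_precision_classes(cm),
    )
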