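"""Pixel-confusion accumulation and segmentation metrics.

A K x K confusion matrix (rows = ground truth, columns = prediction) is
accumulated over label masks; from its per-class TP/TN/FP/FN counts the
two study metrics derive:

* mean pixel accuracy, computed literally as the per-class *binary*
  accuracy averaged over classes,

      mPA = (1/N) * sum_i (TP_i + TN_i) / (TP_i + TN_i + FP_i + FN_i),

  which differs from the global fraction of correctly labelled pixels
  (also exposed, as ``global_accuracy``);

* mean intersection over union,

      mIoU = (1/N) * sum_i TP_i / (TP_i + FP_i + FN_i),

  where classes absent from both prediction and truth (TP+FP+FN = 0) are
  excluded from the mean rather than scored zero.

By default every class — including background (id 0) — enters the means;
``ignore_background=True`` restricts them to the food classes.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["ConfusionMatrix", "accumulate", "mean_pixel_accuracy", "global_accuracy",
           "per_class_iou", "mean_iou", "logits_to_mask", "metrics_report",
           "format_class_table"]


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested from an empty confusion matrix."""


class ConfusionMatrix:
    """K x K pixel-count table; rows = truth class, columns = predicted."""

    def __init__(self, num_classes):
        if num_classes < 2:
            raise ValueError("need at least 2 classes")
        self.num_classes = int(num_classes)
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    @property
    def total(self):
        return int(self.counts.sum())

    def copy(self):
        out = ConfusionMatrix(self.num_classes)
        out.counts[...] = self.counts
        return out

    # per-class derived counts ---------------------------------------------
    def tp(self):
        return np.diag(self.counts).astype(np.int64)

    def fp(self):
        return self.counts.sum(axis=0) - self.tp()

    def fn(self):
        return self.counts.sum(axis=1) - self.tp()

    def tn(self):
        return self.total - self.tp() - self.fp() - self.fn()


def accumulate(pred, truth, cm):
    """Add the pixel confusion of one (pred, truth) mask pair to ``cm``.

    Accumulation is additive: tallying two images equals tallying their
    concatenated pixels.  Empty inputs leave ``cm`` unchanged.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size == 0:
        return cm
    k = cm.num_classes
    for name, arr in (("pred", pred), ("truth", truth)):
        lo, hi = int(arr.min()), int(arr.max())
        if lo < 0 or hi >= k:
            bad = lo if lo < 0 else hi
            raise ValueError(f"{name} contains label {bad} outside [0, {k})")
    idx = truth.astype(np.int64).ravel() * k + pred.astype(np.int64).ravel()
    cm.counts += np.bincount(idx, minlength=k * k).reshape(k, k)
    return cm


def _class_mask(cm, ignore_background):
    mask = np.ones(cm.num_classes, dtype=bool)
    if ignore_background:
        mask[0] = False
    return mask


def mean_pixel_accuracy(cm, ignore_background=False):
    """Per-class binary pixel accuracy averaged over classes (in [0, 1])."""
    if cm.total == 0:
        raise UndefinedMetricError("no pixels accumulated")
    sel = _class_mask(cm, ignore_background)
    tp, tn = cm.tp()[sel], cm.tn()[sel]
    # denominator is the total pixel count for every class
    return float(np.mean((tp + tn) / cm.total))


def global_accuracy(cm):
    """Fraction of all pixels whose predicted class equals the truth."""
    if cm.total == 0:
        raise UndefinedMetricError("no pixels accumulated")
    return float(cm.tp().sum() / cm.total)


def per_class_iou(cm, ignore_background=False):
    """IoU per class; NaN marks classes absent from both pred and truth."""
    if cm.total == 0:
        raise UndefinedMetricError("no pixels accumulated")
    tp, fp, fn = cm.tp(), cm.fp(), cm.fn()
    denom = tp + fp + fn
    iou = np.full(cm.num_classes, np.nan)
    ok = denom > 0
    iou[ok] = tp[ok] / denom[ok]
    if ignore_background:
        iou = iou[1:]
    return iou


def mean_iou(cm, ignore_background=False):
    """Mean IoU over defined classes (undefined classes are excluded)."""
    iou = per_class_iou(cm, ignore_background=ignore_background)
    defined = ~np.isnan(iou)
    if not defined.any():
        raise UndefinedMetricError("every class is undefined (no pixels)")
    return float(iou[defined].mean())


def logits_to_mask(logits):
    """Argmax over the class axis; exact ties resolve to the lowest id."""
    return np.argmax(np.asarray(logits), axis=-1).astype(np.int32)


def metrics_report(cm, class_names=None, ignore_background=False):
    """Full metrics bundle as a JSON-serializable dict."""
    iou = per_class_iou(cm, ignore_background=ignore_background)
    names = class_names
    if names is None:
        offset = 1 if ignore_background else 0
        names = [f"class_{i + offset}" for i in range(len(iou))]
    return {
        "mIoU": mean_iou(cm, ignore_background=ignore_background),
        "mPA": mean_pixel_accuracy(cm, ignore_background=ignore_background),
        "global_accuracy": global_accuracy(cm),
        "per_class_iou": {
            n: (None if np.isnan(v) else float(v)) for n, v in zip(names, iou)
        },
        "pixels": cm.total,
    }


def format_class_table(report):
    """Aligned text table of per-class IoU, ranked highest to lowest."""
    rows = [
        (name, v)
        for name, v in report["per_class_iou"].items()
        if v is not None
    ]
    rows.sort(key=lambda r: -r[1])
    width = max((len(r[0]) for r in rows), default=10)
    lines = [f"{'Class Name':{width}s}  mIoU (%)"]
    for name, v in rows:
        lines.append(f"{name:{width}s}  {100 * v:8.2f}")
    lines.append("")
    lines.append(f"mIoU = {100 * report['mIoU']:.2f}%   mPA = {100 * report['mPA']:.2f}%")
    return "\n".join(lines)


def report_to_json(report, path=None):
    text = json.dumps(report, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
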