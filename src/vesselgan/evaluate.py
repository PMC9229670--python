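"""Segmentation metrics from pooled confusion counts, and k-fold protocol.

All metrics derive from pixelwise true/false positive/negative counts pooled
over a whole validation volume (one number per volume, not a per-slice
average):

    Dice        = 2*TP / (2*TP + FP + FN)
    Precision   = TP / (TP + FP)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

Ratios with an empty denominator are reported as undefined (``None``) rather
than silently zero, so they cannot corrupt fold averages.  The k-fold runner
assigns volume i to fold i (cycling), trains one model per fold on the
remaining volumes and evaluates on the held-out one, then reports per-fold
rows and their unweighted average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import VolumeStack

METRIC_NAMES = ("dice", "precision", "sensitivity", "specificity")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    dice: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _as_binary(x) -> np.ndarray:
    if isinstance(x, VolumeStack):
        x = x.as_array()
    elif hasattr(x, "pixels"):
        x = x.pixels
    x = np.asarray(x)
    if not np.all(np.isin(np.unique(x), (0, 1))):
        raise ValueError("masks must be binary {0,1}")
    return x.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Pixelwise counts pooled over the whole stack."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts) -> float | None:
    den = 2 * c.tp + c.fp + c.fn
    return None if den == 0 else 2 * c.tp / den


def precision(c: ConfusionCounts) -> float | None:
    den = c.tp + c.fp
    return None if den == 0 else c.tp / den


def sensitivity(c: ConfusionCounts) -> float | None:
    den = c.tp + c.fn
    return None if den == 0 else c.tp / den


def specificity(c: ConfusionCounts) -> float | None:
    den = c.tn + c.fp
    return None if den == 0 else c.tn / den


def metrics_report(pred, truth) -> MetricsReport:
    c = confusion_counts(pred, truth)
    return MetricsReport(dice(c), precision(c), sensitivity(c), specificity(c), c)


def dice_set_equivalence(pred, truth) -> float | None:
    """Dice computed directly from pixel sets, 2|A∩B|/(|A|+|B|) — an
    independent route that must agree exactly with the count formula."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    a, b = int(p.sum()), int(t.sum())
    if a + b == 0:
        return None
    return 2 * int(np.count_nonzero(p & t)) / (a + b)


def error_map(pred, truth) -> np.ndarray:
    """|truth - pred|: 1 exactly at misclassified pixels (FP or FN)."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    return (p ^ t).astype(np.uint8)


# ---------------------------------------------------------------------------
# k-fold protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    k: int
    assignment: dict[int, int]  # volume index -> fold index

    def validate(self, n_volumes: int) -> "FoldSplit":
        if set(self.assignment) != set(range(n_volumes)):
            raise ValueError("every volume must be assigned to exactly one fold")
        folds = set(self.assignment.values())
        if folds != set(range(self.k)):
            raise ValueError("every fold must be nonempty")
        return self


def make_fold_split(n_volumes: int, k: int) -> FoldSplit:
    """Deterministic cycling assignment: volume i -> fold i mod k."""
    if k > n_volumes:
        raise ValueError("k must not exceed the number of volumes")
    if k < 1:
        raise ValueError("k must be >= 1")
    return FoldSplit(k, {i: i % k for i in range(n_volumes)}).validate(n_volumes)


def average_row(rows: list[dict]) -> dict:
    """Unweighted mean over folds, per metric; undefined entries are skipped."""
    out = {}
    for name in METRIC_NAMES:
        vals = [r[name] for r in rows if r.get(name) is not None]
        out[name] = float(np.mean(vals)) if vals else None
    return out


def kfold_run(
    volumes: list[tuple[VolumeStack, VolumeStack]],
    k: int,
    train_fn,
) -> pd.DataFrame:
    """Cross-validated evaluation.

    ``train_fn(train_pairs, val_pairs) -> (pred_mask_stack, truth_mask_stack)
    per val volume`` encapsulates training + inference for one fold; this
    function owns only the protocol: the split, the per-fold metric rows and
    the Average row.
    """
    split = make_fold_split(len(volumes), k)
    rows = []
    for fold in range(k):
        val_idx = [i for i, f in split.assignment.items() if f == fold]
        train_idx = [i for i in range(len(volumes)) if i not in val_idx]
        preds = train_fn([volumes[i] for i in train_idx], [volumes[i] for i in val_idx])
        # pool counts over the fold's validation volumes
        fold_counts = ConfusionCounts(0, 0, 0, 0)
        for pred, truth in preds:
            c = confusion_counts(pred, truth)
            fold_counts = ConfusionCounts(
                fold_counts.tp + c.tp, fold_counts.fp + c.fp,
                fold_counts.fn + c.fn, fold_counts.tn + c.tn,
            )
        rows.append({
            "fold": fold + 1,
            "dice": dice(fold_counts),
            "precision": precision(fold_counts),
            "sensitivity": sensitivity(fold_counts),
            "specificity": specificity(fold_counts),
        })
    avg = average_row(rows)
    avg["fold"] = "Average"
    return pd.DataFrame(rows + [avg], columns=["fold", *METRIC_NAMES])
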