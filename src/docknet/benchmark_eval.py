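"""Benchmark evaluation: shuffled negatives, confusion metrics, ROC/AUC and
F-optimal threshold calibration under varying positive:negative ratios.

Conventions (documented, applied everywhere):

* prediction positive iff z >= threshold;
* precision is defined as 0 (with a warning) when no pair is predicted
  positive; F is 0 when precision + recall = 0;
* threshold ties in calibration break toward the LARGEST candidate, i.e.
  fewer predicted positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import canonical_pair

__all__ = [
    "LabeledPair",
    "LabeledPairSet",
    "ConfusionCounts",
    "MetricSet",
    "RocCurve",
    "shuffle_negatives",
    "confusion_at_threshold",
    "metrics",
    "f_measure",
    "roc_auc",
    "calibrate_threshold",
]


@dataclass(frozen=True)
class LabeledPair:
    pair: tuple[str, str]
    z: float
    positive: bool


@dataclass
class LabeledPairSet:
    entries: list[LabeledPair]

    def __post_init__(self):
        pairs = [e.pair for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("pair ids must be unique in a labeled set")

    @property
    def n_pos(self) -> int:
        return sum(e.positive for e in self.entries)

    @property
    def n_neg(self) -> int:
        return sum(not e.positive for e in self.entries)

    @property
    def ratio(self) -> tuple[int, int]:
        return (self.n_pos, self.n_neg)

    @classmethod
    def from_scores(cls, pos_z: Iterable[float], neg_z: Iterable[float]) -> "LabeledPairSet":
        """Convenience constructor with synthetic pair ids."""
        entries = [
            LabeledPair(pair=(f"P{i}a", f"P{i}b"), z=float(z), positive=True)
            for i, z in enumerate(pos_z)
        ]
        entries += [
            LabeledPair(pair=(f"N{i}a", f"N{i}b"), z=float(z), positive=False)
            for i, z in enumerate(neg_z)
        ]
        return cls(entries=entries)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    tpr: float  # recall
    fpr: float
    precision: float
    f_measure: float


def shuffle_negatives(positives: Sequence[tuple[str, str]], n_neg: int, seed: int):
    """Draw ``n_neg`` negative pairs by re-pairing the proteins of the
    positive set.

    Pairs are drawn uniformly without replacement per pair and rejection-
    sampled against positives, self-pairs and duplicates. Deterministic
    given ``seed``.
    """
    pos = {canonical_pair(*p) for p in positives}
    proteins = sorted({p for pair in pos for p in pair})
    n = len(proteins)
    admissible = n * (n - 1) // 2 - len(pos)
    if n_neg > admissible:
        raise ValueError(
            f"requested {n_neg} negatives but only {admissible} admissible "
            f"pairs exist over {n} proteins"
        )
    rng = np.random.default_rng(seed)
    negatives: list[tuple[str, str]] = []
    seen = set(pos)
    while len(negatives) < n_neg:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = canonical_pair(proteins[i], proteins[j])
        if pair in seen:
            continue
        seen.add(pair)
        negatives.append(pair)
    assert not set(negatives) & pos
    return negatives


def confusion_at_threshold(labeled: LabeledPairSet, threshold: float) -> ConfusionCounts:
    """Count TP/FP/TN/FN with prediction positive iff z >= threshold."""
    tp = fp = tn = fn = 0
    for e in labeled.entries:
        pred = e.z >= threshold
        if e.positive:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """TPR, FPR, precision and F-measure from confusion counts.

    TPR = TP/(TP+FN); FPR = FP/(FP+TN); precision = TP/(TP+FP);
    F = 2*precision*recall/(precision+recall).
    """
    if c.n_pos == 0:
        raise ValueError("metrics need at least one positive (TP+FN > 0)")
    tpr = c.tp / c.n_pos
    fpr = c.fp / c.n_neg if c.n_neg > 0 else 0.0
    if c.tp + c.fp == 0:
        warnings.warn("no predicted positives; precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    return MetricSet(tpr=tpr, fpr=fpr, precision=precision,
                     f_measure=f_measure(precision, tpr))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (fpr, tpr), from (0,0) to (1,1)
    auc: float


def roc_auc(labeled: LabeledPairSet) -> RocCurve:
    """ROC over thresholds swept at the distinct observed z values (plus
    infinities); ties grouped; AUC by the trapezoidal rule."""
    n_pos, n_neg = labeled.n_pos, labeled.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    zs = np.array([e.z for e in labeled.entries])
    labels = np.array([e.positive for e in labeled.entries])
    points = [(0.0, 0.0)]
    for t in sorted(np.unique(zs))[::-1]:
        pred = zs >= t
        tpr = float(np.sum(pred & labels)) / n_pos
        fpr = float(np.sum(pred & ~labels)) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=points, auc=auc)


def calibrate_threshold(
    labeled: LabeledPairSet,
    candidates: Sequence[float] | None = None,
) -> tuple[float, MetricSet, pd.DataFrame]:
    """Pick the F-optimal decision threshold.

    Candidates default to the distinct observed z values. Ties in F break
    toward the largest threshold (fewest predicted positives). Returns the
    best threshold, its metrics, and the full sweep table with columns
    (threshold, tpr, fpr, precision, f_measure).
    """
    if labeled.n_pos == 0:
        raise ValueError("calibration needs at least one positive")
    if candidates is None:
        candidates = sorted({e.z for e in labeled.entries})
    thresholds = np.sort(np.asarray(list(candidates), dtype=float))
    pos_z = np.sort([e.z for e in labeled.entries if e.positive])
    neg_z = np.sort([e.z for e in labeled.entries if not e.positive])
    tp = pos_z.size - np.searchsorted(pos_z, thresholds, side="left")
    fp = neg_z.size - np.searchsorted(neg_z, thresholds, side="left")
    tpr = tp / pos_z.size
    fpr = fp / neg_z.size if neg_z.size else np.zeros_like(tp, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        f = np.where(precision + tpr > 0,
                     2.0 * precision * tpr / np.maximum(precision + tpr, 1e-300), 0.0)
    sweep = pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr,
                          "precision": precision, "f_measure": f})
    # idxmax on the reversed column → largest threshold among F ties
    best_idx = int(sweep["f_measure"][::-1].idxmax())
    best = sweep.loc[best_idx]
    best_metrics = MetricSet(tpr=best["tpr"], fpr=best["fpr"],
                             precision=best["precision"], f_measure=best["f_measure"])
    return float(best["threshold"]), best_metrics, sweep
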