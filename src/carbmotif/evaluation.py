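"""Evaluation protocol: confusion metrics, ROC/AUC, stratified k-fold
cross-validation with pooled out-of-fold predictions, repeated negative
resampling, and blind independent testing."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .seq_windows import Dataset, Fragment, sample_negatives


class FragmentClassifier(Protocol):
    """Anything that scores and classifies fragments (combo models,
    single-feature SVM wrappers, profile-threshold models)."""

    def decision_function(self, fragments: Sequence[Fragment]) -> np.ndarray: ...

    def predict(self, fragments: Sequence[Fragment]) -> np.ndarray: ...


ModelFactory = Callable[[Sequence[Fragment], Sequence[Fragment]], FragmentClassifier]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int((y_true & y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    MCC uses the standard denominator
    sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)) and is defined as 0 when any factor
    vanishes.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("metrics need at least one positive and one negative")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom > 0 else 0.0
    return MetricSet(sn=float(sn), sp=float(sp), acc=float(acc), mcc=float(mcc))


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR pairs) and AUC by the rank/trapezoid method,
    with tied scores contributing one half."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return np.column_stack([fpr, tpr]), auc


def cross_validate(
    dataset: Dataset,
    model_factory: ModelFactory,
    k: int = 5,
    seed: int = 0,
) -> tuple[MetricSet, pd.DataFrame]:
    """Stratified k-fold CV; metrics are computed once on the pooled
    out-of-fold predictions (micro-averaged), matching the convention of
    combining the validation folds into a single performance figure.

    Returns the pooled MetricSet (with AUC over pooled decision scores) and
    a per-fragment table of out-of-fold scores and labels.
    """
    frags = list(dataset.positives) + list(dataset.negatives)
    y = np.array([1] * len(dataset.positives) + [0] * len(dataset.negatives))
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise ValueError(f"{k}-fold CV needs at least {k} members per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_scores = np.empty(len(frags))
    oof_pred = np.empty(len(frags), dtype=bool)
    fold_of = np.empty(len(frags), dtype=int)
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(frags)), y)):
        train_pos = [frags[i] for i in tr if y[i] == 1]
        train_neg = [frags[i] for i in tr if y[i] == 0]
        model = model_factory(train_pos, train_neg)
        va_frags = [frags[i] for i in va]
        oof_scores[va] = model.decision_function(va_frags)
        oof_pred[va] = np.asarray(model.predict(va_frags), dtype=bool)
        fold_of[va] = fold
    counts = ConfusionCounts.from_predictions(y == 1, oof_pred)
    metrics = compute_metrics(counts)
    _, metrics.auc = roc_auc(oof_scores, y == 1)
    table = pd.DataFrame(
        {
            "protein_id": [f.source[0] for f in frags],
            "position": [f.source[1] for f in frags],
            "label": y,
            "fold": fold_of,
            "score": oof_scores,
            "predicted": oof_pred.astype(int),
        }
    )
    return metrics, table


def repeated_resampling_eval(
    positives: Sequence[Fragment],
    negative_pool: Sequence[Fragment],
    model_factory: ModelFactory,
    repeats: int = 30,
    ratio: int = 2,
    k: int = 5,
    seed: int = 0,
) -> tuple[MetricSet, pd.DataFrame]:
    """Repeat k-fold CV with freshly resampled negatives and average.

    Each repeat draws ratio x |positives| negatives from the pool (seeded
    independently per repeat from *seed*) and runs a full stratified CV.
    Returns the mean MetricSet and the per-repeat metric table.
    """
    residue = positives[0].center_residue
    base = Dataset(residue=residue, positives=list(positives),
                   negatives=list(negative_pool), n=positives[0].half_width)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        sampled = sample_negatives(base, ratio=ratio, seed=rep_seed)
        metrics, _ = cross_validate(sampled, model_factory, k=k, seed=rep_seed)
        rows.append({"repeat": rep, "seed": rep_seed, **metrics.as_dict()})
    table = pd.DataFrame(rows)
    mean = MetricSet(
        sn=float(table["Sn"].mean()),
        sp=float(table["Sp"].mean()),
        acc=float(table["Acc"].mean()),
        mcc=float(table["MCC"].mean()),
        auc=float(table["AUC"].mean()),
    )
    return mean, table


def independent_test(
    model: FragmentClassifier,
    test_positives: Sequence[Fragment],
    test_negatives: Sequence[Fragment],
) -> MetricSet:
    """Single-pass evaluation on a blind test set.

    If the model records its training sites (a ``training_sources`` set of
    (protein_id, position) pairs), any overlap with the test set raises —
    independent testing must be blind to training data.
    """
    trained_on = getattr(model, "training_sources", None)
    if trained_on is not None:
        test_keys = {f.source for f in test_positives} | {
            f.source for f in test_negatives
        }
        overlap = sorted(test_keys & set(trained_on))
        if overlap:
            raise ValueError(
                f"test set overlaps training data at {len(overlap)} site(s), "
                f"e.g. {overlap[:5]}"
            )
    frags = list(test_positives) + list(test_negatives)
    y = np.array([1] * len(test_positives) + [0] * len(test_negatives))
    pred = np.asarray(model.predict(frags), dtype=bool)
    metrics = compute_metrics(ConfusionCounts.from_predictions(y == 1, pred))
    scores = model.decision_function(frags)
    _, metrics.auc = roc_auc(scores, y == 1)
    return metrics
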