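"""Confusion-matrix metrics and repeated validation schemes.

Metrics use the cancer class (+1) as positive:

    Ac = (TP + TN) / (TP + TN + FP + FN)
    Sn = TP / (TP + FN)
    Sp = TN / (TN + FP)
    CC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

CC is the Matthews correlation of the binary confusion matrix, in
[-1, +1], defined as 0 whenever a factor under the root is zero.

Three validation schemes are provided: repeated stratified five-fold
cross-validation, repeated per-class proportional (80/20) hold-out, and
leave-one-out.  Each repeat pools its held-out predictions into a single
confusion matrix; means and SDs (N-1 denominator) are taken over repeats.

To avoid information leakage, every fold refits the full pipeline —
including the t-filter and any width/component selection — on the
training samples only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .errors import UsageError
from .io import RefinedMatrix

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ValidationReport",
    "confusion",
    "metrics",
    "five_fold_cv",
    "proportional_validation",
    "loocv",
]

_METRIC_ORDER = ("Ac", "CC", "Sn", "Sp")


class Classifier(Protocol):
    """Anything with fit(train_matrix) and predict(test_matrix) -> labels."""

    def fit(self, matrix: RefinedMatrix) -> "Classifier": ...
    def predict(self, matrix: RefinedMatrix) -> np.ndarray: ...


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise UsageError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class MetricSet:
    Ac: float
    CC: float
    Sn: float
    Sp: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in _METRIC_ORDER}


@dataclass
class ValidationReport:
    """Per-repeat metrics plus mean/SD aggregates for one scheme.

    SDs use the sample convention (N-1 denominator); with a single repeat
    the SD is reported as 0.
    """

    scheme: str
    n_repeats: int
    per_repeat: list[MetricSet]
    mean: dict[str, float]
    sd: dict[str, float]
    seed: int | None

    @classmethod
    def from_repeats(
        cls, scheme: str, per_repeat: list[MetricSet], seed: int | None
    ) -> "ValidationReport":
        if not per_repeat:
            raise UsageError("a report needs at least one repeat")
        arr = {m: np.array([getattr(ms, m) for ms in per_repeat]) for m in _METRIC_ORDER}
        mean = {m: float(v.mean()) for m, v in arr.items()}
        sd = {
            m: float(v.std(ddof=1)) if len(per_repeat) > 1 else 0.0
            for m, v in arr.items()
        }
        return cls(scheme, len(per_repeat), per_repeat, mean, sd, seed)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Tally TP/FN/TN/FP with +1 as the positive (cancer) class."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.size != y_pred.size:
        raise UsageError(
            f"length mismatch: {y_true.size} truths vs {y_pred.size} predictions"
        )
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Ac, Sn, Sp and Matthews CC from confusion counts."""
    if c.total == 0:
        raise UsageError("metrics need at least one sample")
    if c.TP + c.FN == 0:
        raise UsageError("sensitivity undefined: no positive samples presented")
    if c.TN + c.FP == 0:
        raise UsageError("specificity undefined: no negative samples presented")
    ac = (c.TP + c.TN) / c.total
    sn = c.TP / (c.TP + c.FN)
    sp = c.TN / (c.TN + c.FP)
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    cc = 0.0 if denom == 0 else (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return MetricSet(Ac=ac, CC=cc, Sn=sn, Sp=sp)


def _check_classes(labels: np.ndarray, minimum: int, what: str) -> None:
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos < minimum or n_neg < minimum:
        raise UsageError(
            f"{what} needs >= {minimum} samples per class "
            f"(got {n_pos} cancer, {n_neg} control)"
        )


def _run_split_repeat(
    pipeline_factory: Callable[[], Classifier],
    matrix: RefinedMatrix,
    splits,
) -> MetricSet:
    """Fit/predict over one repeat's folds, pooling held-out predictions."""
    y = matrix.labels
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    for train_idx, test_idx in splits:
        clf = pipeline_factory()
        clf.fit(matrix.select_samples(train_idx))
        pred = clf.predict(matrix.select_samples(test_idx))
        y_true_all.append(y[test_idx])
        y_pred_all.append(np.asarray(pred))
    return metrics(confusion(np.concatenate(y_true_all), np.concatenate(y_pred_all)))


def five_fold_cv(
    pipeline_factory: Callable[[], Classifier],
    matrix: RefinedMatrix,
    repeats: int = 100,
    seed: int = 0,
    n_folds: int = 5,
) -> ValidationReport:
    """Repeated stratified k-fold cross-validation (default 5-fold x 100).

    Each repeat draws a fresh stratified partition, trains on k-1 folds,
    predicts the held-out fold, and pools all held-out predictions of the
    repeat into one confusion matrix.  Fully reproducible from ``seed``.
    """
    _check_classes(matrix.labels, n_folds, f"{n_folds}-fold CV")
    rng = np.random.SeedSequence(seed)
    repeat_seeds = rng.generate_state(repeats) % (2**31 - 1)
    per_repeat = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(repeat_seeds[r])
        )
        splits = skf.split(matrix.intensities.T, matrix.labels)
        per_repeat.append(_run_split_repeat(pipeline_factory, matrix, splits))
    return ValidationReport.from_repeats(f"{n_folds}-fold-cv", per_repeat, seed)


def proportional_validation(
    pipeline_factory: Callable[[], Classifier],
    matrix: RefinedMatrix,
    train_fraction: float = 0.8,
    repeats: int = 100,
    seed: int = 0,
) -> ValidationReport:
    """Repeated per-class proportional hold-out (default 80/20 x 100).

    Each repeat randomly selects ``train_fraction`` of the controls and of
    the cancers as the training set and tests on the remainder.
    """
    if not 0.0 < train_fraction < 1.0:
        raise UsageError(f"train_fraction must be in (0, 1), got {train_fraction}")
    _check_classes(matrix.labels, 2, "proportional validation")
    rng = np.random.SeedSequence(seed)
    repeat_seeds = rng.generate_state(repeats) % (2**31 - 1)
    per_repeat = []
    for r in range(repeats):
        sss = StratifiedShuffleSplit(
            n_splits=1,
            train_size=train_fraction,
            random_state=int(repeat_seeds[r]),
        )
        splits = sss.split(matrix.intensities.T, matrix.labels)
        per_repeat.append(_run_split_repeat(pipeline_factory, matrix, splits))
    return ValidationReport.from_repeats("proportional", per_repeat, seed)


def loocv(
    pipeline_factory: Callable[[], Classifier],
    matrix: RefinedMatrix,
) -> tuple[MetricSet, list[tuple[str, int, int]]]:
    """Leave-one-out cross-validation.

    Performs n fits, each holding out one sample, pools the n held-out
    predictions into one confusion matrix, and also returns the per-sample
    (sample_id, true, predicted) table.  Deterministic.
    """
    n = matrix.n_samples
    if n < 3:
        raise UsageError(f"LOOCV needs at least 3 samples, got {n}")
    _check_classes(matrix.labels, 1, "LOOCV")
    y = matrix.labels
    preds = np.empty(n, dtype=int)
    table: list[tuple[str, int, int]] = []
    all_idx = np.arange(n)
    for i in range(n):
        train_idx = all_idx[all_idx != i]
        clf = pipeline_factory()
        try:
            clf.fit(matrix.select_samples(train_idx))
            pred = clf.predict(matrix.select_samples([i]))
        except Exception as exc:
            raise UsageError(f"LOOCV failed at held-out sample {i}: {exc}") from exc
        preds[i] = int(np.asarray(pred).ravel()[0])
        table.append((matrix.sample_ids[i], int(y[i]), int(preds[i])))
    return metrics(confusion(y, preds)), table
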