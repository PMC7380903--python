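"""Five-fold cross-validation and the personal/total x sensor ablation grid.

Accuracy follows the counting definition: overall accuracy is correct
windows over total windows (trace of the confusion matrix over its
sum; for two classes this is exactly (TP + TN)/(TP + TN + FP + FN)),
and per-class accuracy is that class's correct windows over its window
count (diagonal entry over row sum).

Two evaluation regimes are compared: PERSONAL (train and test on one
subject's own windows) and TOTAL (train on all subjects' windows
pooled, including the target subject), each under three sensor
subsets (accelerometer, gyroscope, both).  Window-level fold
stratification mirrors the original protocol; because overlapping
windows share frames across folds this is optimistic about
generalization, and a leakage-safe SEGMENT grouping that keeps whole
repetitions together is provided as an alternative.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .classes import ExerciseClass, SensorSubset
from .recognizer import CNNConfig, WindowCNNClassifier, windows_to_tensor
from .sessions import LabeledSession, Window, segment_sessions


class Grouping(enum.Enum):
    WINDOW = "window"  # stratified at window level (protocol-faithful)
    SEGMENT = "segment"  # whole label runs stay in one fold (leakage-safe)


class Regime(enum.Enum):
    PERSONAL = "personal"
    TOTAL = "total"


@dataclasses.dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: list[ExerciseClass]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_pairs(
        cls,
        true: Sequence[int],
        predicted: Sequence[int],
        classes: Sequence[ExerciseClass] = tuple(ExerciseClass),
    ) -> "ConfusionMatrix":
        classes = [ExerciseClass(c) for c in classes]
        index = {int(c): i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, predicted, strict=True):
            counts[index[int(t)], index[int(p)]] += 1
        return cls(counts=counts, classes=classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if [int(c) for c in self.classes] != [int(c) for c in other.classes]:
            raise ValueError("confusion matrices have different class lists")
        return ConfusionMatrix(self.counts + other.counts, list(self.classes))


def compute_accuracy(
    cm: ConfusionMatrix,
) -> tuple[float, dict[ExerciseClass, float]]:
    """Overall and per-class accuracy of a confusion matrix.

    Overall = trace / total.  Per class = diagonal / row sum (correct
    windows of that class over its total); classes with no windows get
    NaN rather than a fabricated rate.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    overall = float(np.trace(cm.counts) / total)
    diag = np.diag(cm.counts).astype(float)
    rows = cm.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per = diag / rows
    per_class = {c: float(per[i]) for i, c in enumerate(cm.classes)}
    return overall, per_class


def check_row_totals(row_counts: Sequence[int], expected_total: int) -> bool:
    """Consistency utility: do per-class window counts sum to the
    stated grand total?"""
    return int(sum(int(c) for c in row_counts)) == int(expected_total)


@dataclasses.dataclass
class EvaluationReport:
    """Result of one cross-validated evaluation cell."""

    regime: Regime
    subset: SensorSubset
    fold_confusions: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    overall_accuracy: float
    per_class_accuracy: dict[ExerciseClass, float]
    fold_assignment: np.ndarray  # fold index per window
    seed: int

    def summary_row(self) -> dict[str, float]:
        out = {c.name: self.per_class_accuracy[c] for c in self.pooled.classes}
        out["TOTAL"] = self.overall_accuracy
        return out


def kfold_split(
    windows: Sequence[Window],
    k: int = 5,
    seed: int = 0,
    grouping: Grouping = Grouping.WINDOW,
) -> list[np.ndarray]:
    """Partition window indices into k folds.

    WINDOW mode stratifies by class at the window level.  SEGMENT mode
    additionally keeps all windows from one contiguous label run in
    the same fold, so overlapping windows of a repetition never split
    across train and test.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(windows) < k:
        raise ValueError(f"need at least k={k} windows, got {len(windows)}")
    y = np.array([int(w.label) for w in windows])
    idx = np.arange(len(windows))
    if grouping is Grouping.WINDOW:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(idx[:, None], y)]
    mapping: dict[tuple[str, int], int] = {}
    group_ids = np.array(
        [mapping.setdefault((w.subject_id, w.segment), len(mapping)) for w in windows]
    )
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(idx[:, None], y, groups=group_ids)]


def cross_validate(
    windows: Sequence[Window],
    subset: SensorSubset,
    config: CNNConfig | None = None,
    k: int = 5,
    grouping: Grouping = Grouping.WINDOW,
    seed: int = 0,
    regime: Regime = Regime.PERSONAL,
) -> EvaluationReport:
    """k-fold cross-validation of the CNN on labeled windows.

    Each fold trains a fresh model on the other k-1 folds (channel
    normalization statistics come from the training folds only, inside
    the estimator's ``fit``) and predicts the held-out fold; the
    pooled confusion matrix is the sum over folds.
    """
    config = config or CNNConfig()
    folds = kfold_split(windows, k=k, seed=seed, grouping=grouping)
    X, y = windows_to_tensor(windows, subset)
    classes = list(ExerciseClass)

    assignment = np.empty(len(windows), dtype=int)
    fold_cms: list[ConfusionMatrix] = []
    for i, test_idx in enumerate(folds):
        assignment[test_idx] = i
        train_mask = np.ones(len(windows), dtype=bool)
        train_mask[test_idx] = False
        est = WindowCNNClassifier(
            conv1_maps=config.conv1_maps,
            conv2_maps=config.conv2_maps,
            dense_units=config.dense_units,
            kernel_size=config.kernel_size,
            pool_size=config.pool_size,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            random_state=config.seed + i,
        ).fit(X[train_mask], y[train_mask])
        pred = est.predict(X[test_idx])
        fold_cms.append(ConfusionMatrix.from_pairs(y[test_idx], pred, classes))

    pooled = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled = pooled + cm
    overall, per_class = compute_accuracy(pooled)
    return EvaluationReport(
        regime=regime,
        subset=subset,
        fold_confusions=fold_cms,
        pooled=pooled,
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        fold_assignment=assignment,
        seed=seed,
    )


def run_ablation(
    sessions_by_subject: Mapping[str, Sequence[LabeledSession]],
    target_subject: str,
    config: CNNConfig | None = None,
    k: int = 5,
    grouping: Grouping = Grouping.WINDOW,
    seed: int = 0,
    stride_samples: int = 5,
    include_target_in_total: bool = True,
) -> dict[tuple[Regime, SensorSubset], EvaluationReport]:
    """The 2 regime x 3 sensor-subset evaluation grid for one subject.

    PERSONAL cells cross-validate on the target subject's own windows;
    TOTAL cells on all subjects' windows pooled (including the target,
    matching the original definition of the total data set; pass
    ``include_target_in_total=False`` for a leave-the-user's-data-out
    variant, which is NOT the original protocol).
    """
    if target_subject not in sessions_by_subject:
        raise ValueError(f"unknown target subject {target_subject!r}")
    if len(sessions_by_subject) < 2:
        raise ValueError("the TOTAL regime needs at least 2 subjects")

    personal = segment_sessions(
        sessions_by_subject[target_subject], stride_samples=stride_samples
    )
    pooled_sessions = [
        s
        for subj, sess in sessions_by_subject.items()
        for s in sess
        if include_target_in_total or subj != target_subject
    ]
    pooled = segment_sessions(pooled_sessions, stride_samples=stride_samples)

    grid: dict[tuple[Regime, SensorSubset], EvaluationReport] = {}
    for regime, windows in ((Regime.PERSONAL, personal), (Regime.TOTAL, pooled)):
        for subset in SensorSubset:
            grid[(regime, subset)] = cross_validate(
                windows, subset, config=config, k=k, grouping=grouping,
                seed=seed, regime=regime,
            )
    return grid


def ablation_table(
    grid: Mapping[tuple[Regime, SensorSubset], EvaluationReport],
) -> pd.DataFrame:
    """Summary table: per-class rows plus a Total row, one column per
    (regime, subset) cell, accuracies as percentages.

    Display convention: per-class cells round to 1 decimal place,
    the Total row to 2 (use the returned full-precision frame for any
    further arithmetic).
    """
    columns = {}
    for (regime, subset), report in grid.items():
        col = {
            c.name: 100.0 * report.per_class_accuracy[c]
            for c in report.pooled.classes
        }
        col["Total"] = 100.0 * report.overall_accuracy
        columns[(regime.value, subset.name)] = col
    df = pd.DataFrame(columns)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["regime", "subset"])
    order = [c.name for c in ExerciseClass] + ["Total"]
    return df.loc[order]
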