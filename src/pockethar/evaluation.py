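"""Confusion matrices and accuracy summaries.

Rows are the performed activity, columns the recognized one, both in
canonical activity order. Per-class accuracy is the diagonal cell over
its row total; the headline "average" is the unweighted (macro) mean of
the six per-class accuracies — identical to micro-accuracy only when
the test set is balanced. Accuracies render at one decimal in percent
using round-half-even.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from pockethar.errors import ConfigError, DimensionError, FormatError
from pockethar.features import FeatureExtractionConfig, extract_features
from pockethar.mlp_classifier import MLPModel, predict
from pockethar.types import ACTIVITIES, Activity
from pockethar.windowing import SensorWindow


@dataclass
class ConfusionMatrix:
    """6x6 performed-vs-recognized counts."""

    counts: np.ndarray
    labels: tuple[Activity, ...] = ACTIVITIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise DimensionError(
                f"confusion matrix must be {k}x{k}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ConfigError("confusion counts must be nonnegative")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[Activity, Activity]]
    ) -> "ConfusionMatrix":
        idx = {a: i for i, a in enumerate(ACTIVITIES)}
        counts = np.zeros((len(ACTIVITIES), len(ACTIVITIES)), dtype=np.int64)
        for true, pred in pairs:
            counts[idx[true], idx[pred]] += 1
        return cls(counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AccuracyReport:
    """Per-class accuracies, their macro average, and false positives."""

    per_class: dict[Activity, float]
    average: float
    false_positives: dict[Activity, int] = field(default_factory=dict)


def accuracy_report(matrix: ConfusionMatrix) -> AccuracyReport:
    """Derive per-class accuracy, macro average and FP tallies.

    Classes with no evaluated windows (zero row total) are left out of
    ``per_class`` and of the macro average.
    """
    per_class: dict[Activity, float] = {}
    false_positives: dict[Activity, int] = {}
    diag = np.diag(matrix.counts)
    rows = matrix.row_totals
    cols = matrix.column_totals
    for i, label in enumerate(matrix.labels):
        if rows[i]:
            per_class[label] = float(diag[i] / rows[i])
        false_positives[label] = int(cols[i] - diag[i])
    if not per_class:
        raise ConfigError("no evaluated windows in confusion matrix")
    average = float(np.mean(list(per_class.values())))
    return AccuracyReport(per_class, average, false_positives)


def evaluate(
    model: MLPModel,
    windows: Sequence[SensorWindow],
    feature_config: FeatureExtractionConfig = FeatureExtractionConfig(),
) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Featurize, predict and tally each labeled window."""
    pairs = []
    for i, window in enumerate(windows):
        if window.label is None:
            raise ConfigError(f"window {i} has no activity label")
        scores = predict(model, extract_features(window, feature_config))
        pairs.append((window.label, scores.predicted))
    matrix = ConfusionMatrix.from_pairs(pairs)
    return matrix, accuracy_report(matrix)


# ---------------------------------------------------------------------------
# text rendering
# ---------------------------------------------------------------------------

_COL = 12


def render_report(matrix: ConfusionMatrix, report: AccuracyReport) -> str:
    """Fixed-width performed-vs-recognized table plus an accuracy line."""
    names = [a.value for a in matrix.labels]
    lines = []
    header = "performed".ljust(_COL) + "".join(n.rjust(_COL) for n in names)
    lines.append(header)
    for i, name in enumerate(names):
        lines.append(
            name.ljust(_COL)
            + "".join(str(int(c)).rjust(_COL) for c in matrix.counts[i])
        )
    lines.append(
        "total".ljust(_COL)
        + "".join(str(int(c)).rjust(_COL) for c in matrix.column_totals)
    )
    acc = "  ".join(
        f"{a.value}={100 * report.per_class[a]:.1f}%"
        for a in matrix.labels
        if a in report.per_class
    )
    lines.append(f"accuracy  {acc}  average={100 * report.average:.1f}%")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> ConfusionMatrix:
    """Recover the confusion matrix from :func:`render_report` output."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("performed"):
        raise FormatError("report does not start with a 'performed' header")
    names = lines[0].split()[1:]
    try:
        labels = tuple(Activity(n) for n in names)
    except ValueError as exc:
        raise FormatError(f"unknown activity in report header: {exc}") from None
    rows = []
    for label in labels:
        row_line = next(
            (ln for ln in lines[1:] if ln.split()[0] == label.value), None
        )
        if row_line is None:
            raise FormatError(f"missing row for '{label.value}'")
        rows.append([int(tok) for tok in row_line.split()[1:]])
    return ConfusionMatrix(np.array(rows, dtype=np.int64), labels)
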