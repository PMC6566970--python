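"""The paired count/percentage confusion-matrix statistic.

The report is an ``(NC + 1) x (NC + 1)`` table ``F = [f_ij]`` over an
``NC x NC`` count block ``N`` with **rows = predicted class** and
**columns = true (target) class**; ``P`` is the number of scored samples.
Every cell is a pair:

* inner cell ``(i, j)``           -> ``(N_ij, N_ij / P)``
* last column (``j = NC + 1``)    -> ``(precision_i, 1 - precision_i)``
  with ``precision_i = N_ii / sum_j N_ij``  (row sum)
* last row (``i = NC + 1``)       -> ``(recall_j, 1 - recall_j)``
  with ``recall_j = N_jj / sum_i N_ij``     (column sum)
* corner                          -> ``(accuracy, error)``
  with ``accuracy = sum_i N_ii / P``.

Counts and ``P`` are stored exactly; all derived values keep full
precision, with rounding (half-up) applied only when rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "overall_accuracy",
    "render_confusion",
]


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Count block plus the derived paired-cell structure.

    ``counts[i, j]`` is the number of samples of true class ``j + 1``
    predicted as class ``i + 1``.
    """

    counts: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            cf = np.asarray(counts, dtype=np.float64)
            if not np.all(cf == np.round(cf)):
                raise ValueError("counts must be integers")
            counts = cf.astype(np.int64)
        if counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if self.class_names is not None and len(self.class_names) != counts.shape[0]:
            raise ValueError("one class name per class required")

    @classmethod
    def from_counts(
        cls, counts, class_names: list[str] | None = None
    ) -> "ConfusionMatrix":
        return cls(counts=np.asarray(counts), class_names=class_names)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        """P — the total number of scored samples."""
        return int(self.counts.sum())

    @property
    def precision(self) -> np.ndarray:
        """Per predicted-class precision ``N_ii / row sum`` (0 if empty row)."""
        row = self.counts.sum(axis=1)
        diag = np.diag(self.counts)
        out = np.zeros(self.n_classes)
        empty = row == 0
        if np.any(empty):
            warnings.warn(
                "precision undefined for classes never predicted; reporting 0",
                RuntimeWarning,
                stacklevel=2,
            )
        out[~empty] = diag[~empty] / row[~empty]
        return out

    @property
    def recall(self) -> np.ndarray:
        """Per true-class recall ``N_jj / column sum`` (0 if empty column)."""
        col = self.counts.sum(axis=0)
        diag = np.diag(self.counts)
        out = np.zeros(self.n_classes)
        empty = col == 0
        if np.any(empty):
            warnings.warn(
                "recall undefined for classes never observed; reporting 0",
                RuntimeWarning,
                stacklevel=2,
            )
        out[~empty] = diag[~empty] / col[~empty]
        return out

    @property
    def accuracy(self) -> float:
        """Overall accuracy ``trace / P``."""
        total = self.total
        if total == 0:
            raise ValueError("confusion matrix is empty (P = 0)")
        return float(np.trace(self.counts) / total)

    def table(self) -> np.ndarray:
        """The full ``(NC+1) x (NC+1) x 2`` paired-cell structure.

        Inner pairs are ``(count, share of P)``; margins are
        ``(rate, 1 - rate)`` for precision / recall / overall accuracy.
        """
        nc = self.n_classes
        total = self.total
        if total == 0:
            raise ValueError("confusion matrix is empty (P = 0)")
        out = np.zeros((nc + 1, nc + 1, 2))
        out[:nc, :nc, 0] = self.counts
        out[:nc, :nc, 1] = self.counts / total
        prec, rec = self.precision, self.recall
        out[:nc, nc, 0] = prec
        out[:nc, nc, 1] = 1.0 - prec
        out[nc, :nc, 0] = rec
        out[nc, :nc, 1] = 1.0 - rec
        acc = self.accuracy
        out[nc, nc] = (acc, 1.0 - acc)
        return out

    def transposed(self) -> "ConfusionMatrix":
        """Swap predictions and truths (transposes counts, swaps
        precision and recall)."""
        return ConfusionMatrix(counts=self.counts.T, class_names=self.class_names)

    def to_delimited(self, delimiter: str = "\t", decimals: int = 2) -> str:
        """Machine-readable export of the full paired structure."""
        names = self.class_names or [
            f"class_{i + 1}" for i in range(self.n_classes)
        ]
        tab = self.table()
        nc = self.n_classes
        lines = [delimiter.join(["", *names, "Precision"])]
        for i in range(nc):
            cells = [names[i]]
            for j in range(nc):
                pct = _round_half_up(100 * tab[i, j, 1], decimals)
                cells.append(f"{int(tab[i, j, 0])}/{pct:.{decimals}f}%")
            p = _round_half_up(100 * tab[i, nc, 0], decimals)
            q = _round_half_up(100 * tab[i, nc, 1], decimals)
            cells.append(f"{p:.{decimals}f}%/{q:.{decimals}f}%")
            lines.append(delimiter.join(cells))
        cells = ["Recall"]
        for j in range(nc + 1):
            p = _round_half_up(100 * tab[nc, j, 0], decimals)
            q = _round_half_up(100 * tab[nc, j, 1], decimals)
            cells.append(f"{p:.{decimals}f}%/{q:.{decimals}f}%")
        lines.append(delimiter.join(cells))
        return "\n".join(lines)


def confusion_matrix(
    true_labels,
    predicted_labels,
    n_classes: int,
    class_names: list[str] | None = None,
) -> ConfusionMatrix:
    """Tally 1-based label vectors into the confusion structure.

    Rows index the predicted class, columns the true class.
    """
    y_true = np.asarray(true_labels, dtype=np.int64)
    y_pred = np.asarray(predicted_labels, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 1 or y.max() > n_classes):
            raise ValueError(
                f"{name} labels out of range 1..{n_classes}: "
                f"observed {int(y.min())}..{int(y.max())}"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_pred - 1, y_true - 1), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace of the count block divided by P, as a fraction in [0, 1]."""
    return cm.accuracy


def render_confusion(cm: ConfusionMatrix, decimals: int = 2) -> str:
    """Fixed-layout text table with ``count / percent`` paired cells.

    Percentages are rounded half-up to ``decimals`` for display only.
    """
    names = cm.class_names or [f"class_{i + 1}" for i in range(cm.n_classes)]
    tab = cm.table()
    nc = cm.n_classes

    def pct(x: float) -> str:
        return f"{_round_half_up(100 * x, decimals):.{decimals}f}%"

    rows: list[list[str]] = []
    rows.append(["", *names, "Precision"])
    for i in range(nc):
        cells = [names[i]]
        for j in range(nc):
            cells.append(f"{int(tab[i, j, 0])} / {pct(tab[i, j, 1])}")
        cells.append(f"{pct(tab[i, nc, 0])} / {pct(tab[i, nc, 1])}")
        rows.append(cells)
    last = ["Recall"]
    for j in range(nc + 1):
        last.append(f"{pct(tab[nc, j, 0])} / {pct(tab[nc, j, 1])}")
    rows.append(last)

    widths = [max(len(r[c]) for r in rows) for c in range(nc + 2)]
    return "\n".join(
        "  ".join(cell.rjust(widths[c]) for c, cell in enumerate(row))
        for row in rows
    )
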