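"""Worked-example confusion counts from the six-activity smartphone benchmark.

These small integer tables are reported results of cascade-ensemble runs on
the public smartphone activity-recognition test split (2947 windows, six
activities) — one from the handcrafted-feature pipeline and one from the
FFT-magnitude pipeline — plus the right/wrong totals of a run on the
12-class extension with postural transitions (3162 test windows).  They
serve as fixed inputs for exercising the confusion-matrix statistic:
feeding them through :mod:`celearn.metrics` must reproduce the published
precision / recall / overall-accuracy figures exactly.

Orientation: rows = predicted class, columns = true class.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ACTIVITY_NAMES",
    "HANDCRAFTED_COUNTS",
    "FFT_COUNTS",
    "TWELVE_CLASS_CORRECT",
    "TWELVE_CLASS_TOTAL",
    "counts_to_labels",
    "twelve_class_labels",
]

ACTIVITY_NAMES = ["Walking", "Upstairs", "Downstairs", "Sitting", "Standing", "Lying"]

#: Handcrafted-feature pipeline test confusion counts (P = 2947).
HANDCRAFTED_COUNTS = np.array(
    [
        [492, 22, 4, 0, 0, 0],
        [1, 448, 17, 0, 0, 0],
        [3, 1, 399, 0, 0, 0],
        [0, 0, 0, 464, 17, 0],
        [0, 0, 0, 27, 515, 0],
        [0, 0, 0, 0, 0, 537],
    ],
    dtype=np.int64,
)

#: FFT-magnitude pipeline test confusion counts (P = 2947).
FFT_COUNTS = np.array(
    [
        [493, 3, 12, 0, 0, 0],
        [1, 464, 27, 1, 0, 0],
        [2, 4, 381, 0, 0, 0],
        [0, 0, 0, 432, 12, 0],
        [0, 0, 0, 58, 520, 0],
        [0, 0, 0, 0, 0, 537],
    ],
    dtype=np.int64,
)

#: Right/wrong totals of the 12-class (activities + postural transitions) run.
TWELVE_CLASS_CORRECT = 3007
TWELVE_CLASS_TOTAL = 3162
TWELVE_CLASS_N_CLASSES = 12


def counts_to_labels(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand a count block into 1-based (true, predicted) label vectors.

    Any expansion with the same counts is equivalent for tallying; rows are
    emitted in (predicted, true) cell order.
    """
    counts = np.asarray(counts, dtype=np.int64)
    true_parts, pred_parts = [], []
    nc = counts.shape[0]
    for i in range(nc):  # predicted
        for j in range(nc):  # true
            c = int(counts[i, j])
            if c:
                true_parts.append(np.full(c, j + 1, dtype=np.int64))
                pred_parts.append(np.full(c, i + 1, dtype=np.int64))
    return np.concatenate(true_parts), np.concatenate(pred_parts)


def twelve_class_labels() -> tuple[np.ndarray, np.ndarray]:
    """A 12-class labeling with exactly the reported right/wrong totals.

    Only the right/wrong totals of the 12-class run are published, so any
    labeling with ``TWELVE_CLASS_CORRECT`` agreements reproduces its
    overall accuracy: true labels cycle round-robin over the 12 classes and
    the final ``TWELVE_CLASS_TOTAL - TWELVE_CLASS_CORRECT`` predictions are
    shifted to the next class.
    """
    n, nc = TWELVE_CLASS_TOTAL, TWELVE_CLASS_N_CLASSES
    y_true = (np.arange(n) % nc) + 1
    y_pred = y_true.copy()
    wrong = n - TWELVE_CLASS_CORRECT
    y_pred[-wrong:] = (y_true[-wrong:] % nc) + 1
    return y_true, y_pred
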