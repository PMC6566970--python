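"""Core in-memory containers shared across the package.

Three array-backed containers move through every pipeline stage:

* :class:`FeatureTable` — an ``n x d`` real feature matrix with optional
  1-based integer activity labels; the unit of supervised learning.
* :class:`RawWindowSet` — an ``n x C x L`` tensor of fixed-length sensor
  windows (C channels, L samples per window), e.g. 2.56 s windows of
  triaxial accelerometer + gyroscope streams sampled at 50 Hz.
* :class:`ProbabilityMatrix` — an ``n x NC`` matrix of per-sample class
  distributions ("class vectors"), the currency of the cascade.

Labels are 1-based externally (matching the plain-text dataset dialect the
package reads and writes) and mapped to 0-based indices internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureTable",
    "RawWindowSet",
    "ProbabilityMatrix",
    "DEFAULT_CHANNEL_NAMES",
]

#: Channel order of the six inertial signals (triaxial total acceleration
#: followed by triaxial body angular velocity).
DEFAULT_CHANNEL_NAMES: tuple[str, ...] = (
    "total_acc_x",
    "total_acc_y",
    "total_acc_z",
    "body_gyro_x",
    "body_gyro_y",
    "body_gyro_z",
)


def _as_2d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must be non-empty, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or Inf values")
    return arr


@dataclass
class FeatureTable:
    """An ``n x d`` feature matrix with optional 1-based integer labels."""

    features: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list[str] | None = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        self.features = _as_2d_float(self.features, "features")
        n, d = self.features.shape
        if self.labels is not None:
            y = np.asarray(self.labels)
            if y.ndim != 1 or y.shape[0] != n:
                raise ValueError(
                    f"labels must be a length-{n} vector, got shape {y.shape}"
                )
            if not np.issubdtype(y.dtype, np.integer):
                yf = np.asarray(y, dtype=np.float64)
                if not np.all(yf == np.round(yf)):
                    raise ValueError("labels must be integers")
                y = yf.astype(np.int64)
            else:
                y = y.astype(np.int64)
            if y.min() < 1:
                raise ValueError("labels must be 1-based (minimum observed < 1)")
            nc = self.n_classes if self.n_classes is not None else int(y.max())
            if y.max() > nc:
                raise ValueError(
                    f"label {int(y.max())} out of range 1..{nc}"
                )
            self.labels = y
            self.n_classes = nc
        if self.feature_names is not None and len(self.feature_names) != d:
            raise ValueError(
                f"feature_names has {len(self.feature_names)} entries for {d} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def class_labels(self) -> np.ndarray:
        """All class labels ``1..NC`` as an integer array."""
        if self.n_classes is None:
            raise ValueError("table has no labels and no declared n_classes")
        return np.arange(1, self.n_classes + 1)

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("operation requires a labeled table")
        return self.labels


@dataclass
class RawWindowSet:
    """An ``n x C x L`` tensor of fixed-length multichannel sensor windows."""

    values: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES
    sampling_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"values must be 3-dimensional, got shape {arr.shape}")
        n, c, length = arr.shape
        if c < 1:
            raise ValueError("need at least one channel")
        if length < 2:
            raise ValueError("window length must be at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("window values contain NaN or Inf")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        self.values = arr

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def window_length(self) -> int:
        return self.values.shape[2]


@dataclass
class ProbabilityMatrix:
    """Per-sample class distributions over classes ``class_labels``.

    Rows are probability vectors: entries in [0, 1] summing to 1 within
    1e-9.  ``class_labels`` records the 1-based class each column refers to.
    """

    values: np.ndarray
    class_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = _as_2d_float(self.values, "probabilities")
        if self.class_labels is None:
            self.class_labels = np.arange(1, arr.shape[1] + 1)
        self.class_labels = np.asarray(self.class_labels, dtype=np.int64)
        if self.class_labels.shape != (arr.shape[1],):
            raise ValueError("class_labels length must equal number of columns")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-9:
            raise ValueError("probabilities outside [0, 1]")
        row_sums = arr.sum(axis=1)
        if np.max(np.abs(row_sums - 1.0)) > 1e-9:
            raise ValueError("probability rows must sum to 1 within 1e-9")
        self.values = np.clip(arr, 0.0, 1.0)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def argmax_labels(self) -> np.ndarray:
        """Most probable class per row; ties resolve to the smallest label."""
        return self.class_labels[np.argmax(self.values, axis=1)]
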