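"""Reading the plain-text sensor-dataset dialect and persisting models.

The public smartphone HAR datasets ship as whitespace-delimited text:
``X_train.txt`` holds one row of real features per sample, ``y_train.txt``
one integer activity label per line, and ``Inertial Signals/`` one file per
sensor channel with one 128-sample window per row.  The readers here accept
any run of whitespace as a delimiter, never reorder rows, and raise
format errors that name the offending line.

Model persistence wraps :mod:`pickle` in a self-describing container with a
format tag and schema version, so a stale or truncated file fails loudly
instead of being silently misread.
"""

from __future__ import annotations

import os
import pickle
from pathlib import Path

import numpy as np

from .containers import DEFAULT_CHANNEL_NAMES, FeatureTable, RawWindowSet

__all__ = [
    "DataFormatError",
    "ModelIOError",
    "read_feature_table",
    "read_inertial_signals",
    "save_model",
    "load_model",
]


class DataFormatError(ValueError):
    """A text input file does not conform to the expected dialect."""


class ModelIOError(RuntimeError):
    """A persisted model file is unreadable, corrupt, or version-mismatched."""


_MODEL_FORMAT = "celearn.cascade-model"
_SCHEMA_VERSION = 1


def _read_matrix(path: Path) -> np.ndarray:
    """Parse a whitespace-delimited real matrix, reporting bad lines."""
    rows: list[list[float]] = []
    width: int | None = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue  # blank lines (e.g. trailing newline) are ignored
            try:
                row = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise DataFormatError(
                    f"{path}: non-numeric token on line {lineno}"
                ) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise DataFormatError(
                    f"{path}: line {lineno} has {len(row)} values, "
                    f"expected {width}"
                )
            rows.append(row)
    if not rows:
        raise DataFormatError(f"{path}: file contains no data rows")
    return np.asarray(rows, dtype=np.float64)


def read_feature_table(
    x_path: str | os.PathLike,
    y_path: str | os.PathLike | None = None,
    n_classes: int | None = None,
) -> FeatureTable:
    """Read a feature matrix and (optionally) its label file.

    ``n_classes``, when given, declares the label range ``1..NC`` and label
    values outside it raise :class:`DataFormatError`.  Row order is
    preserved exactly as on disk.
    """
    x_path = Path(x_path)
    features = _read_matrix(x_path)

    labels = None
    if y_path is not None:
        y_path = Path(y_path)
        raw = _read_matrix(y_path)
        if raw.shape[1] != 1:
            raise DataFormatError(
                f"{y_path}: expected one label per line, found {raw.shape[1]} columns"
            )
        if not np.all(raw == np.round(raw)):
            raise DataFormatError(f"{y_path}: labels must be integers")
        labels = raw[:, 0].astype(np.int64)
        if labels.shape[0] != features.shape[0]:
            raise DataFormatError(
                f"{y_path} has {labels.shape[0]} labels but {x_path} has "
                f"{features.shape[0]} rows"
            )
        lo = int(labels.min())
        hi = int(labels.max())
        if lo < 1 or (n_classes is not None and hi > n_classes):
            raise DataFormatError(
                f"{y_path}: label out of range 1..{n_classes or hi} "
                f"(observed {lo}..{hi})"
            )

    return FeatureTable(features=features, labels=labels, n_classes=n_classes)


def read_inertial_signals(
    directory: str | os.PathLike,
    channel_names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES,
    split: str = "train",
    window_length: int = 128,
    sampling_rate_hz: float = 50.0,
) -> RawWindowSet:
    """Read per-channel window files into an ``n x C x L`` tensor.

    Expects ``<directory>/<channel>_<split>.txt`` for every requested
    channel, each with the same number of rows and ``window_length``
    columns.  Channels are stacked in the order given, so permuting
    ``channel_names`` permutes the tensor identically.
    """
    directory = Path(directory)
    mats = []
    for name in channel_names:
        path = directory / f"{name}_{split}.txt"
        if not path.exists():
            raise DataFormatError(f"missing channel file: {path}")
        mat = _read_matrix(path)
        if mat.shape[1] != window_length:
            raise DataFormatError(
                f"{path}: expected {window_length} columns per row, "
                f"found {mat.shape[1]}"
            )
        mats.append(mat)
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) != 1:
        raise DataFormatError(
            f"channel files disagree on row counts: {sorted(n_rows)}"
        )
    tensor = np.stack(mats, axis=1)
    return RawWindowSet(
        values=tensor,
        channel_names=tuple(channel_names),
        sampling_rate_hz=sampling_rate_hz,
    )


def save_model(model, path: str | os.PathLike) -> None:
    """Persist a fitted model in a version-tagged container."""
    payload = {
        "format": _MODEL_FORMAT,
        "schema_version": _SCHEMA_VERSION,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)


def load_model(path: str | os.PathLike):
    """Load a model saved by :func:`save_model`.

    Raises :class:`ModelIOError` on truncation, foreign content, or a
    schema-version mismatch — never a silent misread.  The reloaded model
    predicts bit-identically to the saved one.
    """
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError, ValueError) as exc:
        raise ModelIOError(f"{path}: truncated or corrupt model file") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelIOError(f"{path}: not a recognised model container")
    version = payload.get("schema_version")
    if version != _SCHEMA_VERSION:
        raise ModelIOError(
            f"{path}: schema version {version} unsupported "
            f"(this build reads version {_SCHEMA_VERSION})"
        )
    return payload["model"]
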