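"""The two randomized-tree ensembles, by contract.

Both families average the per-tree class distributions into one
probability vector per sample; they differ in exactly two ways:

* ``gini_bagged`` — each tree is grown on a bootstrap resample and each
  split optimizes the Gini criterion over a random candidate subset of
  ``sqrt(d)`` features (the classic Random Forest recipe).
* ``fully_random`` — each tree is grown on the *full* training sample and
  every split uses a single uniformly drawn candidate feature with a
  random cut (the completely-random-tree recipe used by cascade forests).

Backends delegate to scikit-learn's RandomForestClassifier and
ExtraTreesClassifier, which implement exactly these contracts with seeded
determinism; predictions are re-indexed onto the full 1..NC class set so a
fold that never saw some class still emits a complete class vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier

from ..containers import FeatureTable, ProbabilityMatrix

__all__ = ["ForestSpec", "ForestModel", "fit_forest", "predict_forest"]

_FAMILIES = ("gini_bagged", "fully_random")


@dataclass(frozen=True)
class ForestSpec:
    """Family, size and seed of a randomized-tree ensemble."""

    family: str = "gini_bagged"
    n_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")


@dataclass
class ForestModel:
    estimator: RandomForestClassifier | ExtraTreesClassifier
    spec: ForestSpec
    class_labels: np.ndarray
    n_features: int


def _make_estimator(spec: ForestSpec):
    if spec.family == "gini_bagged":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            random_state=spec.seed,
            n_jobs=1,
        )
    return ExtraTreesClassifier(
        n_estimators=spec.n_trees,
        criterion="gini",
        max_features=1,
        bootstrap=False,
        random_state=spec.seed,
        n_jobs=1,
    )


def fit_forest(
    table: FeatureTable,
    spec: ForestSpec,
    class_labels: np.ndarray | None = None,
) -> ForestModel:
    """Fit one randomized-tree ensemble on a labeled table."""
    spec.validate()
    labels = table.require_labels()
    if class_labels is None:
        class_labels = table.class_labels
    est = _make_estimator(spec)
    est.fit(table.features, labels)
    return ForestModel(
        estimator=est,
        spec=spec,
        class_labels=np.asarray(class_labels, dtype=np.int64),
        n_features=table.n_features,
    )


def predict_forest(model: ForestModel, features) -> ProbabilityMatrix:
    """Mean of the per-tree class distributions over the full class set."""
    X = features.features if isinstance(features, FeatureTable) else np.asarray(
        features, dtype=np.float64
    )
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"features must be n x {model.n_features}, got shape {X.shape}"
        )
    raw = model.estimator.predict_proba(X)
    seen = model.estimator.classes_.astype(np.int64)
    full = np.zeros((X.shape[0], model.class_labels.shape[0]))
    col = {int(c): j for j, c in enumerate(model.class_labels)}
    for j_seen, c in enumerate(seen):
        full[:, col[int(c)]] = raw[:, j_seen]
    return ProbabilityMatrix(values=full, class_labels=model.class_labels)
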