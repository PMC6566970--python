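"""Uniform learner interface over the four classifier families.

The cascade treats its members uniformly: a :class:`LearnerSpec` names a
family (``boosted_trees``, ``gini_bagged``, ``fully_random`` or
``softmax``) with keyword parameters; :func:`make_learner` instantiates a
fresh adapter exposing

    fit(table, class_labels, seed) -> fitted adapter
    predict_proba(features) -> ProbabilityMatrix

Presets bundle the hyper-parameter sets used for the two feature
pipelines: ``handcrafted`` (booster with 30 rounds, depth 3, shrinkage
0.1) for precomputed feature tables and ``fft`` (200 rounds, depth 5) for
frequency-magnitude features; both use 500-tree forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..containers import FeatureTable, ProbabilityMatrix
from . import boosting, forests, softmax

__all__ = [
    "LearnerSpec",
    "make_learner",
    "default_learner_specs",
    "PRESETS",
]

#: Fixed classifier order used everywhere a layer's vectors are concatenated.
_DEFAULT_ORDER = ("boosted_trees", "gini_bagged", "fully_random", "softmax")


@dataclass(frozen=True)
class LearnerSpec:
    """A classifier family plus its constructor parameters."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; "
                             f"choose from {sorted(_KINDS)}")


class _BoostedAdapter:
    def __init__(self, **params: Any):
        self.params = params
        self.model: boosting.BoostedTreesModel | None = None

    def fit(self, table: FeatureTable, class_labels=None, seed: int = 0):
        self.model = boosting.fit_boosted(
            table, class_labels=class_labels, seed=seed, **self.params
        )
        return self

    def predict_proba(self, features) -> ProbabilityMatrix:
        assert self.model is not None, "learner is not fitted"
        return boosting.predict_boosted(self.model, features)


class _SoftmaxAdapter:
    def __init__(self, **params: Any):
        self.params = params
        self.model: softmax.SoftmaxModel | None = None

    def fit(self, table: FeatureTable, class_labels=None, seed: int = 0):
        self.model = softmax.fit_softmax(
            table, class_labels=class_labels, seed=seed, **self.params
        )
        return self

    def predict_proba(self, features) -> ProbabilityMatrix:
        assert self.model is not None, "learner is not fitted"
        return softmax.softmax_probabilities(self.model, features)


class _ForestAdapter:
    def __init__(self, family: str, **params: Any):
        self.family = family
        self.params = params
        self.model: forests.ForestModel | None = None

    def fit(self, table: FeatureTable, class_labels=None, seed: int = 0):
        spec = forests.ForestSpec(
            family=self.family,
            n_trees=self.params.get("n_trees", 500),
            seed=seed,
        )
        self.model = forests.fit_forest(table, spec, class_labels=class_labels)
        return self

    def predict_proba(self, features) -> ProbabilityMatrix:
        assert self.model is not None, "learner is not fitted"
        return forests.predict_forest(self.model, features)


_KINDS = {
    "boosted_trees": lambda params: _BoostedAdapter(**params),
    "softmax": lambda params: _SoftmaxAdapter(**params),
    "gini_bagged": lambda params: _ForestAdapter("gini_bagged", **params),
    "fully_random": lambda params: _ForestAdapter("fully_random", **params),
}


def make_learner(spec: LearnerSpec):
    """Instantiate a fresh, unfitted adapter for ``spec``."""
    spec.validate()
    return _KINDS[spec.kind](dict(spec.params))


def default_learner_specs(
    preset: str = "handcrafted",
    n_trees: int = 500,
    kinds: tuple[str, ...] = _DEFAULT_ORDER,
) -> tuple[LearnerSpec, ...]:
    """The four classifier specs in their fixed concatenation order.

    ``preset`` selects the booster size: ``handcrafted`` (30 rounds,
    depth 3) or ``fft`` (200 rounds, depth 5), both with shrinkage 0.1.
    ``kinds`` may name a subset (in order) for reduced combinations.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    booster = PRESETS[preset]
    by_kind = {
        "boosted_trees": LearnerSpec("boosted_trees", dict(booster)),
        "gini_bagged": LearnerSpec("gini_bagged", {"n_trees": n_trees}),
        "fully_random": LearnerSpec("fully_random", {"n_trees": n_trees}),
        "softmax": LearnerSpec(
            "softmax",
            {"learning_rate": 0.1, "l2_strength": 1e-4, "n_iterations": 500},
        ),
    }
    unknown = set(kinds) - set(by_kind)
    if unknown:
        raise ValueError(f"unknown learner kinds: {sorted(unknown)}")
    return tuple(by_kind[k] for k in kinds)


#: Booster hyper-parameters per feature pipeline.
PRESETS: dict[str, dict[str, Any]] = {
    "handcrafted": {"n_rounds": 30, "max_depth": 3, "learning_rate": 0.1},
    "fft": {"n_rounds": 200, "max_depth": 5, "learning_rate": 0.1},
}
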