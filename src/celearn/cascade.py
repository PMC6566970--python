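"""The cascade ensemble: layered stacking of four classifiers.

Each cascade layer holds four heterogeneous classifiers (second-order
boosted trees, a Gini/bootstrap forest, a completely-random forest, and
softmax regression).  For every training sample, each classifier produces
a "class vector" — an estimated probability distribution over the NC
activity classes — via seeded k-fold cross validation, so the vectors a
sample contributes downstream never come solely from a model that
memorized it.  The four class vectors (``4 * NC`` columns; 24 for six
classes) are concatenated with the *original* features to form the next
layer's input, keeping the width constant from layer 2 on.

Two readings of the k-fold augmentation are supported:

* ``literal_k_minus_1`` (default) — a sample's vector is the average of
  the ``k - 1`` fold models whose training part contained it;
* ``out_of_fold`` — a sample's vector is the single prediction of the one
  model that held it out (classic stacking).

A layer's accuracy is the fused (mean of four matrices, argmax) CV
prediction scored against the training labels.  Training stops when that
accuracy has not improved on the best layer for ``patience`` consecutive
layers (or at ``max_layers``); prediction propagates through layers
``1..best_layer_index`` and fuses at the best layer.  At test time each
classifier's vector is, per configuration, the mean prediction of its K
fold models (default — the same models that produced the training-time
augmentation) or the prediction of a full-data refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .containers import FeatureTable, ProbabilityMatrix
from .learners import LearnerSpec, default_learner_specs, make_learner

__all__ = [
    "CascadeConfig",
    "LayerModel",
    "CascadeModel",
    "cv_class_vectors",
    "fuse",
    "augment",
    "fit_cascade",
    "predict_cascade",
]

_AUG_MODES = ("literal_k_minus_1", "out_of_fold")
_TEST_MODES = ("average_fold_models", "refit_full")


@dataclass(frozen=True)
class CascadeConfig:
    """Everything that determines a cascade fit, seeds included."""

    k_folds: int = 5
    patience: int = 3
    max_layers: int = 20
    seed: int = 0
    augmentation_mode: str = "literal_k_minus_1"
    test_time_fold_handling: str = "average_fold_models"
    learner_specs: tuple[LearnerSpec, ...] = field(
        default_factory=default_learner_specs
    )

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.max_layers < 1:
            raise ValueError("max_layers must be at least 1")
        if self.augmentation_mode not in _AUG_MODES:
            raise ValueError(f"augmentation_mode must be one of {_AUG_MODES}")
        if self.test_time_fold_handling not in _TEST_MODES:
            raise ValueError(
                f"test_time_fold_handling must be one of {_TEST_MODES}"
            )
        if len(self.learner_specs) < 1:
            raise ValueError("need at least one learner spec")
        for spec in self.learner_specs:
            spec.validate()

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["learner_specs"] = [
            {"kind": s.kind, "params": dict(s.params)} for s in self.learner_specs
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CascadeConfig":
        d = dict(d)
        specs = d.pop("learner_specs", None)
        if specs is not None:
            d["learner_specs"] = tuple(
                LearnerSpec(kind=s["kind"], params=dict(s.get("params", {})))
                for s in specs
            )
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class LayerModel:
    """One fitted cascade layer."""

    fold_models: list[list[Any]]  # [learner][fold]
    full_models: list[Any] | None  # per learner, only for refit_full
    fold_of: np.ndarray  # training-sample -> fold index
    cv_vectors: list[ProbabilityMatrix]  # per learner, over the training set
    layer_cv_accuracy: float


@dataclass
class CascadeModel:
    """A trained cascade: fitted layers plus the selected depth."""

    layers: list[LayerModel]
    best_layer_index: int  # 1-based
    n_classes: int
    original_dim: int
    config: CascadeConfig
    layer_accuracies: list[float] = field(default_factory=list)


def _derived_seed(*parts: int) -> int:
    """A deterministic sub-seed below 2**31 from integer components."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _fold_assignment(
    labels: np.ndarray, k: int, seed: int, n_classes: int
) -> np.ndarray:
    """Seeded random partition into k near-equal folds.

    Falls back to a stratified partition if some fold's *training*
    complement would contain fewer than two classes; raises if even
    stratification cannot fix it.
    """
    n = labels.shape[0]
    if k > n:
        raise ValueError(f"k_folds={k} exceeds n_samples={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_of[chunk] = f

    def training_parts_ok(assign: np.ndarray) -> bool:
        return all(
            np.unique(labels[assign != f]).shape[0] >= 2 for f in range(k)
        )

    if training_parts_ok(fold_of):
        return fold_of

    # Stratified fallback: spread each class round-robin over folds.
    fold_of = np.empty(n, dtype=np.int64)
    offset = 0
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        idx = rng.permutation(idx)
        fold_of[idx] = (np.arange(idx.shape[0]) + offset) % k
        offset += idx.shape[0]
    if not training_parts_ok(fold_of):
        raise ValueError(
            "cannot build folds whose training parts all contain >= 2 classes"
        )
    return fold_of


def cv_class_vectors(
    learner_spec: LearnerSpec,
    table: FeatureTable,
    k: int = 5,
    mode: str = "literal_k_minus_1",
    seed: int = 0,
    fold_of: np.ndarray | None = None,
) -> tuple[ProbabilityMatrix, list[Any], np.ndarray]:
    """K-fold class vectors for one classifier over the training set.

    Returns ``(vectors, fold_models, fold_of)``.  Every fold model predicts
    the whole training set once; a sample's vector is then either the mean
    of the ``k - 1`` models that trained on it (``literal_k_minus_1``) or
    the one prediction of the model that held it out (``out_of_fold``).
    """
    if mode not in _AUG_MODES:
        raise ValueError(f"mode must be one of {_AUG_MODES}")
    labels = table.require_labels()
    nc = table.n_classes
    class_labels = table.class_labels
    if fold_of is None:
        fold_of = _fold_assignment(labels, k, seed, nc)
    if int(fold_of.max()) + 1 != k:
        raise ValueError("fold assignment does not match k")

    n = table.n_samples
    sum_all = np.zeros((n, nc))
    heldout = np.empty((n, nc))
    fold_models: list[Any] = []
    for f in range(k):
        train = fold_of != f
        sub = FeatureTable(
            features=table.features[train],
            labels=labels[train],
            n_classes=nc,
        )
        model = make_learner(learner_spec).fit(
            sub, class_labels=class_labels, seed=_derived_seed(seed, f)
        )
        preds = model.predict_proba(table.features).values
        sum_all += preds
        heldout[fold_of == f] = preds[fold_of == f]
        fold_models.append(model)

    if mode == "out_of_fold":
        values = heldout
    else:
        values = (sum_all - heldout) / (k - 1)
    return (
        ProbabilityMatrix(values=values, class_labels=class_labels),
        fold_models,
        fold_of,
    )


def fuse(vectors: list[ProbabilityMatrix]) -> tuple[ProbabilityMatrix, np.ndarray]:
    """Arithmetic mean of the classifiers' probability matrices.

    Returns the fused matrix and its argmax labels (ties go to the
    smallest class label).
    """
    if not vectors:
        raise ValueError("nothing to fuse")
    first = vectors[0]
    for v in vectors[1:]:
        if v.values.shape != first.values.shape or not np.array_equal(
            v.class_labels, first.class_labels
        ):
            raise ValueError("fused matrices must share shape and class order")
    mean = np.mean([v.values for v in vectors], axis=0)
    fused = ProbabilityMatrix(values=mean, class_labels=first.class_labels)
    return fused, fused.argmax_labels()


def augment(
    original: FeatureTable, layer_vectors: list[ProbabilityMatrix]
) -> FeatureTable:
    """Concatenate original features with the layer's class vectors.

    Column layout: the original ``d`` columns, then each classifier's NC
    probability columns in the layer's fixed classifier order.
    """
    n = original.n_samples
    blocks = [original.features]
    names = list(
        original.feature_names
        or [f"x_{j:04d}" for j in range(original.n_features)]
    )
    for i, pm in enumerate(layer_vectors):
        if pm.n_samples != n:
            raise ValueError(
                f"class-vector block {i} has {pm.n_samples} rows, expected {n}"
            )
        blocks.append(pm.values)
        names.extend(
            f"clf{i}_class{int(c)}" for c in pm.class_labels
        )
    return FeatureTable(
        features=np.hstack(blocks),
        labels=original.labels,
        feature_names=names,
        n_classes=original.n_classes,
    )


def fit_cascade(table: FeatureTable, config: CascadeConfig) -> CascadeModel:
    """Train the cascade with automatic depth selection.

    Layer 1 consumes the original features; every later layer consumes the
    originals concatenated with the previous layer's CV class vectors.
    Training stops once the best layer accuracy has gone ``patience``
    consecutive layers without improving, or at ``max_layers``.
    """
    config.validate()
    labels = table.require_labels()
    if table.n_classes < 2:
        raise ValueError("cascade training requires at least 2 classes")

    original = table
    current = table
    layers: list[LayerModel] = []
    accuracies: list[float] = []
    best_acc = -np.inf
    best_idx = 0
    stall = 0
    refit_full = config.test_time_fold_handling == "refit_full"

    for layer_i in range(1, config.max_layers + 1):
        fold_seed = _derived_seed(config.seed, layer_i, 0)
        fold_of = _fold_assignment(labels, config.k_folds, fold_seed, table.n_classes)
        vectors: list[ProbabilityMatrix] = []
        fold_models: list[list[Any]] = []
        full_models: list[Any] | None = [] if refit_full else None
        for li, spec in enumerate(config.learner_specs):
            pm, models, _ = cv_class_vectors(
                spec,
                current,
                k=config.k_folds,
                mode=config.augmentation_mode,
                seed=_derived_seed(config.seed, layer_i, li + 1),
                fold_of=fold_of,
            )
            vectors.append(pm)
            fold_models.append(models)
            if refit_full:
                full = make_learner(spec).fit(
                    current,
                    class_labels=original.class_labels,
                    seed=_derived_seed(config.seed, layer_i, li + 1, 997),
                )
                full_models.append(full)
        _, fused_labels = fuse(vectors)
        acc = float(np.mean(fused_labels == labels))
        layers.append(
            LayerModel(
                fold_models=fold_models,
                full_models=full_models,
                fold_of=fold_of,
                cv_vectors=vectors,
                layer_cv_accuracy=acc,
            )
        )
        accuracies.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_idx = layer_i
            stall = 0
        else:
            stall += 1
        if stall >= config.patience:
            break
        current = augment(original, vectors)

    return CascadeModel(
        layers=layers,
        best_layer_index=best_idx,
        n_classes=original.n_classes,
        original_dim=original.n_features,
        config=config,
        layer_accuracies=accuracies,
    )


def _layer_test_vectors(
    model: CascadeModel, layer: LayerModel, features: np.ndarray
) -> list[ProbabilityMatrix]:
    class_labels = np.arange(1, model.n_classes + 1)
    vectors = []
    if model.config.test_time_fold_handling == "refit_full":
        assert layer.full_models is not None
        for full in layer.full_models:
            vectors.append(full.predict_proba(features))
        return vectors
    for models in layer.fold_models:
        mean = np.mean(
            [m.predict_proba(features).values for m in models], axis=0
        )
        vectors.append(ProbabilityMatrix(values=mean, class_labels=class_labels))
    return vectors


def predict_cascade(
    model: CascadeModel, features
) -> tuple[np.ndarray, ProbabilityMatrix]:
    """Propagate new samples through layers ``1..best_layer_index``.

    Augmentation mirrors training: each intermediate layer's test-time
    class vectors are concatenated with the original test features.
    Returns ``(labels, fused probability matrix)``; labels are never
    consulted — only feature values flow through.
    """
    X = features.features if isinstance(features, FeatureTable) else np.asarray(
        features, dtype=np.float64
    )
    if X.ndim != 2 or X.shape[1] != model.original_dim:
        raise ValueError(
            f"features must be n x {model.original_dim}, got shape {X.shape}"
        )
    original = FeatureTable(features=X, n_classes=model.n_classes)
    current = X
    for li in range(model.best_layer_index):
        layer = model.layers[li]
        vectors = _layer_test_vectors(model, layer, current)
        if li == model.best_layer_index - 1:
            fused, labels = fuse(vectors)
            return labels, fused
        current = augment(original, vectors).features
    raise RuntimeError("cascade has no layers")  # pragma: no cover
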