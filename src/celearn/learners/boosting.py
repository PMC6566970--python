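"""Second-order gradient-boosted decision trees with a softmax link.

The booster minimizes a regularized objective

    Obj = sum_i l(y_i, yhat_i) + sum_k [ (lambda/2) ||w_k||^2 + gamma T_k ],

where ``l`` is the multiclass softmax (cross-entropy) loss and each
``f_k`` is a regression tree with ``T_k`` leaves and leaf scores ``w_k``.
Each boosting round takes a second-order Taylor expansion of the loss at
the current scores, yielding per-sample gradient statistics ``g_i`` and
``h_i``; one tree per class is grown greedily.  For a fixed leaf partition
with sums ``G_j = sum g_i`` and ``H_j = sum h_i`` over leaf ``j``:

    optimal leaf score   w_j* = -G_j / (H_j + lambda)
    structure score      Obj(q) = -1/2 sum_j G_j^2 / (H_j + lambda) + gamma T
    split gain           1/2 [G_L^2/(H_L+l) + G_R^2/(H_R+l)
                               - (G_L+G_R)^2/(H_L+H_R+l)] - gamma

Splits are exact: every midpoint between consecutive distinct sorted
feature values is scored, ties broken by (lowest feature index, lowest
threshold).  Scores start at zero for every class, so an unboosted model
predicts the uniform distribution; each round adds the shrinkage-scaled
(``learning_rate``) tree outputs to the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..containers import FeatureTable, ProbabilityMatrix

__all__ = [
    "GradientStats",
    "Tree",
    "BoostedTreesModel",
    "leaf_weight",
    "split_gain",
    "build_tree",
    "structure_score",
    "softmax_loss_gradients",
    "fit_boosted",
    "predict_boosted",
]


@dataclass
class GradientStats:
    """First- and second-order loss derivatives per training sample."""

    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.float64)
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.g.shape != self.h.shape or self.g.ndim != 1:
            raise ValueError("g and h must be 1-d arrays of equal length")
        if np.any(self.h < 0):
            raise ValueError("second-order statistics must be non-negative")


def leaf_weight(G: float, H: float, reg_lambda: float) -> float:
    """Optimal score of a leaf with gradient sums ``(G, H)``."""
    denom = H + reg_lambda
    if denom <= 0:
        raise ValueError("H + lambda must be positive")
    return -G / denom


def split_gain(
    GL: float,
    HL: float,
    GR: float,
    HR: float,
    reg_lambda: float,
    gamma: float,
) -> float:
    """Loss reduction of splitting a node into (L, R) child leaves."""
    if HL + reg_lambda <= 0 or HR + reg_lambda <= 0:
        raise ValueError("child H + lambda must be positive")
    parent = (GL + GR) ** 2 / (HL + HR + reg_lambda)
    return 0.5 * (GL**2 / (HL + reg_lambda) + GR**2 / (HR + reg_lambda) - parent) - gamma


@dataclass
class Tree:
    """A binary regression tree stored as parallel node arrays.

    Internal node ``i`` routes ``x`` left iff
    ``x[feature[i]] <= threshold[i]``.  Leaves have ``feature[i] == -1`` and
    carry their optimal (unshrunk) score in ``value[i]``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))

    def leaf_of(self, X: np.ndarray) -> np.ndarray:
        """Node index of the leaf each row of ``X`` falls into."""
        X = np.asarray(X, dtype=np.float64)
        node = np.zeros(X.shape[0], dtype=np.int64)
        # Iterate until every sample sits on a leaf; depth-bounded loop.
        while True:
            feat = self.feature[node]
            active = feat >= 0
            if not np.any(active):
                return node
            rows = np.nonzero(active)[0]
            go_left = X[rows, feat[rows]] <= self.threshold[node[rows]]
            node[rows] = np.where(
                go_left, self.left[node[rows]], self.right[node[rows]]
            )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.leaf_of(X)]


class _TreeGrower:
    """Greedy exact-split tree construction with a shared feature presort.

    Sorting each feature column once per dataset and filtering the sorted
    order by node membership makes per-node split search O(n d) instead of
    O(n log n d), which matters when thousands of small trees share one
    training matrix (one tree per class per round per CV fold).
    """

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=np.float64)
        self.order = np.argsort(self.X, axis=0, kind="stable")

    def grow(
        self,
        stats: GradientStats,
        max_depth: int,
        reg_lambda: float,
        gamma: float,
    ) -> Tree:
        g, h = stats.g, stats.h
        n, d = self.X.shape
        if g.shape[0] != n:
            raise ValueError("gradient statistics length must match n_samples")
        feature: list[int] = []
        threshold: list[float] = []
        left: list[int] = []
        right: list[int] = []
        value: list[float] = []

        def new_node() -> int:
            feature.append(-1)
            threshold.append(np.nan)
            left.append(-1)
            right.append(-1)
            value.append(0.0)
            return len(feature) - 1

        def best_split(mask: np.ndarray):
            G = float(g[mask].sum())
            H = float(h[mask].sum())
            best = None  # (gain, feat, thr)
            for j in range(d):
                oj = self.order[:, j]
                idx = oj[mask[oj]]
                if idx.shape[0] < 2:
                    break  # node is a singleton; same for every feature
                xs = self.X[idx, j]
                gl = np.cumsum(g[idx])[:-1]
                hl = np.cumsum(h[idx])[:-1]
                valid = xs[1:] > xs[:-1]
                if not np.any(valid):
                    continue
                gains = 0.5 * (
                    gl**2 / (hl + reg_lambda)
                    + (G - gl) ** 2 / (H - hl + reg_lambda)
                    - G**2 / (H + reg_lambda)
                ) - gamma
                gains[~valid] = -np.inf
                i = int(np.argmax(gains))
                if best is None or gains[i] > best[0]:
                    best = (float(gains[i]), j, float(0.5 * (xs[i] + xs[i + 1])))
            return G, H, best

        def build(mask: np.ndarray, depth: int) -> int:
            nid = new_node()
            G, H, best = best_split(mask)
            if depth >= max_depth or best is None or best[0] <= 0.0:
                value[nid] = leaf_weight(G, H, reg_lambda)
                return nid
            _, j, thr = best
            go_left = mask & (self.X[:, j] <= thr)
            go_right = mask & ~go_left
            feature[nid] = j
            threshold[nid] = thr
            left[nid] = build(go_left, depth + 1)
            right[nid] = build(go_right, depth + 1)
            return nid

        build(np.ones(n, dtype=bool), 0)
        return Tree(
            feature=np.asarray(feature, dtype=np.int64),
            threshold=np.asarray(threshold, dtype=np.float64),
            left=np.asarray(left, dtype=np.int64),
            right=np.asarray(right, dtype=np.int64),
            value=np.asarray(value, dtype=np.float64),
        )


def build_tree(
    stats: GradientStats,
    features: np.ndarray,
    max_depth: int = 3,
    reg_lambda: float = 1.0,
    gamma: float = 0.0,
) -> Tree:
    """Grow one regression tree greedily on gradient statistics.

    Growth stops at ``max_depth``, at singleton nodes, or when the best
    achievable split gain is non-positive; leaves carry their optimal
    scores ``-G/(H + lambda)``.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be non-negative")
    return _TreeGrower(np.atleast_2d(features)).grow(
        stats, max_depth, reg_lambda, gamma
    )


def structure_score(
    tree: Tree,
    stats: GradientStats,
    features: np.ndarray,
    reg_lambda: float = 1.0,
    gamma: float = 0.0,
) -> float:
    """Closed-form objective value of the tree's leaf partition,
    ``-1/2 sum_j G_j^2/(H_j + lambda) + gamma T``."""
    leaves = tree.leaf_of(np.atleast_2d(features))
    score = 0.0
    for leaf in np.unique(leaves):
        in_leaf = leaves == leaf
        G = float(stats.g[in_leaf].sum())
        H = float(stats.h[in_leaf].sum())
        score -= 0.5 * G**2 / (H + reg_lambda)
    return score + gamma * tree.n_leaves


def softmax_loss_gradients(
    scores: np.ndarray, y_onehot: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-class (g, h) of the softmax loss at ``scores``.

    ``g = p - y`` and ``h = p (1 - p)``, the diagonal of the Hessian.
    """
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=1, keepdims=True)
    return p - y_onehot, p * (1.0 - p)


@dataclass
class BoostedTreesModel:
    """A fitted booster: ``trees[t][c]`` is round ``t``'s tree for class c."""

    trees: list[list[Tree]]
    class_labels: np.ndarray
    n_rounds: int
    max_depth: int
    learning_rate: float
    reg_lambda: float
    gamma: float
    n_features: int
    train_loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def fit_boosted(
    table: FeatureTable,
    n_rounds: int = 30,
    max_depth: int = 3,
    learning_rate: float = 0.1,
    reg_lambda: float = 1.0,
    gamma: float = 0.0,
    seed: int | None = None,
    class_labels: np.ndarray | None = None,
) -> BoostedTreesModel:
    """Fit the multiclass booster: one tree per class per round.

    Scores start at zero, so ``n_rounds = 0`` predicts uniform
    probabilities.  ``train_loss_trace[t]`` is the mean softmax loss after
    ``t`` rounds.  The procedure is deterministic; ``seed`` exists for
    interface uniformity.
    """
    labels = table.require_labels()
    if class_labels is None:
        class_labels = table.class_labels
    class_labels = np.asarray(class_labels, dtype=np.int64)
    nc = class_labels.shape[0]
    if nc < 2:
        raise ValueError("boosting requires at least 2 classes")
    if n_rounds < 0:
        raise ValueError("n_rounds must be non-negative")

    X = table.features
    n = X.shape[0]
    col = {int(c): j for j, c in enumerate(class_labels)}
    y = np.zeros((n, nc))
    y[np.arange(n), [col[int(v)] for v in labels]] = 1.0

    grower = _TreeGrower(X)
    scores = np.zeros((n, nc))
    trees: list[list[Tree]] = []
    trace = np.empty(n_rounds + 1)
    for t in range(n_rounds + 1):
        p = _softmax_rows(scores)
        trace[t] = float(-np.mean(np.sum(y * np.log(np.clip(p, 1e-300, None)), axis=1)))
        if t == n_rounds:
            break
        g = p - y
        h = p * (1.0 - p)
        round_trees = []
        for c in range(nc):
            tree = grower.grow(
                GradientStats(g=g[:, c], h=h[:, c]), max_depth, reg_lambda, gamma
            )
            scores[:, c] += learning_rate * tree.value[tree.leaf_of(X)]
            round_trees.append(tree)
        trees.append(round_trees)

    return BoostedTreesModel(
        trees=trees,
        class_labels=class_labels,
        n_rounds=n_rounds,
        max_depth=max_depth,
        learning_rate=learning_rate,
        reg_lambda=reg_lambda,
        gamma=gamma,
        n_features=X.shape[1],
        train_loss_trace=trace,
    )


def predict_boosted(model: BoostedTreesModel, features) -> ProbabilityMatrix:
    """Sum shrunk tree outputs per class and pass through the softmax map."""
    X = features.features if isinstance(features, FeatureTable) else np.asarray(
        features, dtype=np.float64
    )
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"features must be n x {model.n_features}, got shape {X.shape}"
        )
    scores = np.zeros((X.shape[0], model.class_labels.shape[0]))
    for round_trees in model.trees:
        for c, tree in enumerate(round_trees):
            scores[:, c] += model.learning_rate * tree.predict(X)
    return ProbabilityMatrix(
        values=_softmax_rows(scores), class_labels=model.class_labels
    )
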