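"""Train a cascade ensemble on a synthetic six-class task.

Generates a six-class Gaussian-blob feature table (the stand-in for a
precomputed activity-feature matrix), fits the four-classifier cascade
with 5-fold class-vector augmentation, and reports the per-layer CV
accuracies, the automatically selected depth, and held-out test accuracy.
Small learner sizes keep the demo under a minute.
"""

import numpy as np

import celearn as ce
from celearn.learners import LearnerSpec

train = ce.make_feature_table(ce.SynthSpec(n_samples=900, seed=0))
test = ce.make_feature_table(ce.SynthSpec(n_samples=450, seed=1000))
print(f"train: {train.n_samples} x {train.n_features}, "
      f"{train.n_classes} classes")

config = ce.CascadeConfig(
    k_folds=5,
    patience=3,
    max_layers=6,
    seed=0,
    learner_specs=(
        LearnerSpec("boosted_trees", {"n_rounds": 15, "max_depth": 3}),
        LearnerSpec("gini_bagged", {"n_trees": 60}),
        LearnerSpec("fully_random", {"n_trees": 60}),
        LearnerSpec("softmax", {"n_iterations": 300}),
    ),
)
model = ce.fit_cascade(train, config)

for i, acc in enumerate(model.layer_accuracies, start=1):
    marker = "  <- best" if i == model.best_layer_index else ""
    print(f"layer {i}: cv accuracy {100 * acc:.2f}%{marker}")
print(f"depth selected automatically: {model.best_layer_index} "
      f"(stopped after {len(model.layers)} layers; patience "
      f"{config.patience})")
print(f"every layer past the first consumed "
      f"{train.n_features} + 4 x {train.n_classes} = "
      f"{train.n_features + 4 * train.n_classes} features")

labels, _ = ce.predict_cascade(model, test)
acc = np.mean(labels == test.labels)
print(f"held-out test accuracy: {100 * acc:.2f}% on {test.n_samples} samples")
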