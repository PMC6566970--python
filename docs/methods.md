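# Methods

## Model

`celearn` is a cascade (layered stacking) ensemble for multiclass
classification of wearable-sensor windows.  Layer ℓ receives an input
matrix `X_ℓ`; four classifiers each produce, for every training sample,
an estimated class distribution ("class vector") via seeded k-fold cross
validation; the four n×NC matrices are concatenated with the *original*
features to form `X_{ℓ+1} = [X_1 | P_boost | P_rf | P_et | P_softmax]`.
Only the immediately preceding layer's vectors are carried, so the width
is constant (d + 4·NC) from layer 2 on.  The fixed concatenation order is
boosted trees, bagged-Gini forest, completely-random forest, softmax.

A layer's score is the accuracy of the fused CV prediction — the
arithmetic mean of the four probability matrices, argmax per row, ties to
the smallest class label — against the training labels.  The mean-then-
argmax fusion is the standard cascade-forest convention; nothing else in
the architecture depends on it.  Training stops when the best layer
score has not improved for `patience` consecutive layers (default 3) or
at `max_layers` (default 20); the best layer (earliest on ties) is the
prediction depth.

### Class-vector generation

Two readings of the k-fold augmentation are first-class and tested:

* `literal_k_minus_1` (default): a sample's vector is the mean of the
  k−1 fold models whose training part contained it.  These are partly
  in-sample predictions; with memorizing learners the layer CV accuracy
  is optimistic, which mainly affects how quickly the plateau rule
  fires, not test-time behaviour.
* `out_of_fold`: the single prediction of the model that held the sample
  out — classic stacked generalization.

Folds are a seeded random partition into k near-equal parts; if some
fold's training complement would contain fewer than two classes the
partition falls back to a stratified one, and errors out if even that
fails.  At test time each classifier's vector is, by default, the mean
prediction of its k fold models (`average_fold_models`) — the same
models that produced the training-time augmentation, keeping feature
distributions matched between training and prediction.  A full-data
refit per classifier (`refit_full`) is available.

Test labels are never consulted during prediction; depth selection uses
training-set CV accuracy only, so no held-out information leaks into
model selection.

### Base learners

**Boosted trees (from scratch).**  Additive model over K rounds, one
regression tree per class per round, scores starting at zero (so an
unboosted model predicts uniform probabilities).  The multiclass softmax
loss is expanded to second order; per sample and class, `g = p − y`,
`h = p(1 − p)` (the diagonal Hessian).  Trees are grown greedily with
exact split search: every midpoint between consecutive distinct sorted
feature values is scored by the regularized gain; growth stops at
`max_depth`, at singletons, or when the best gain is ≤ 0; leaf scores
are the closed-form optimum `−G/(H+λ)`, added to the class scores scaled
by the shrinkage η.  Ties in gain break to the lowest feature index,
then the lowest threshold, making training fully deterministic.  A
per-dataset column presort is shared across all trees of a fit, so
per-node split search is O(nd).  Defaults: λ = 1, γ = 0; K = 30,
depth 3, η = 0.1 for precomputed feature tables, and K = 200, depth 5,
η = 0.1 for FFT-magnitude inputs (frequency features are individually
weaker, needing more and deeper trees).  Histogram/approximate splits,
column subsampling and sparsity handling are deliberately out of scope.

**Softmax regression (from scratch).**  `p(y=k|x) ∝ exp(w_kᵀx)` with a
bias column appended; fitting maximizes the penalized mean
log-likelihood `J(w) = (1/m) Σ log p(y_i|x_i) − (λ/2)‖w‖²` by full-batch
gradient ascent `w ← w + α[(1/m) Σ x_i(1[y_i=j] − p_ij) − λw_j]` from
`w = 0`.  The sign convention is fixed by requiring the likelihood to
increase (one common statement of the update carries an extra minus sign
that would descend it).  All probability evaluations subtract the
row-wise maximum score before exponentiating — mathematically a no-op,
numerically overflow-proof.  Defaults: α = 0.1, λ = 1e−4, 500
iterations; these are not prescribed by the model family and were chosen
as conventional values at which the objective trace is monotone on the
package's synthetic tasks.

**Randomized forests (scikit-learn backends).**  The contract is: both
families average per-tree class distributions; `gini_bagged` uses
bootstrap resamples and Gini-optimal splits over √d random candidate
features (`RandomForestClassifier`); `fully_random` uses the full sample
for every tree and a single uniformly random candidate feature per split
(`ExtraTreesClassifier(max_features=1, bootstrap=False)` — the
completely-random-tree convention of cascade forests; the contract fixes
"random feature among all features" but not the candidate-set size, and
one is the maximally random choice).  500 trees by default.  Fold models
re-index predictions onto the full 1..NC class set so a fold missing a
class still emits complete vectors.

### FFT features

Per channel, the unnormalized DFT of the 128-sample window, per-bin
modulus, channels concatenated in order: 6×128 → 768 features, exactly
the input dimension (the conjugate-symmetric half is redundant for real
signals but is kept to preserve dimension).  `|DFT|` is circular-shift
invariant, which is the point: windowed periodic movement is phase-
arbitrary.  No windowing functions or band summaries are applied; the
windows are taken as given (already denoised upstream).

### Confusion report

(NC+1)×(NC+1) paired cells over a count block with rows = predicted
class, columns = true class: inner cells (count, count/P); last column
(precision, 1−precision) with precision read along a predicted-class
row; last row (recall, 1−recall) down a true-class column; corner
(accuracy, error).  Counts are exact integers; percentages are rounded
half-up to 2 decimals at rendering only.  Empty rows/columns yield
precision/recall 0 with a warning (they arise only in degenerate tests).

## Synthetic data

The generator defines the study conditions for every test.

**Feature tables** are class-conditional Gaussian blobs: NC informative
axes (class k centred at `sep/√2 · e_k`, so center distances equal
`class_separation` exactly), remaining columns pure noise; labels are a
symmetric multinomial draw (redrawn from the same stream in the rare
zero-count event), 1-based.  Defaults — NC = 6, d = 24 (6 informative +
18 noise), separation 4.0, within-class sd 1.0 — put a single well-tuned
learner near 90% test accuracy, the regime of the real six-activity
benchmark.  What this does *not* emulate: feature correlation, subject
heterogeneity, non-Gaussian class shapes, and the near-linear-separability
structure of real HAR feature sets; passing tests demonstrate the
architecture's mechanics and relative orderings, not real-data accuracy.

**Raw windows** are per-channel unit-amplitude sinusoids at an integer
DFT bin determined by (class, channel), uniformly random phase per
window and channel, plus Gaussian noise.  Distinct bins per class within
each channel make classes exactly separable in magnitude space; the
random phase makes the class-conditional distribution of every
individual time sample identical across classes (zero-mean, arcsine-
shaped), so a *linear* classifier on raw samples is provably at chance.
Amplitude is deliberately constant across classes: any class-dependent
amplitude leaks into time-domain marginal variances and would let even a
linear probe discriminate.  Note a subtlety the tests document: each
class's noiseless windows form a one-dimensional phase manifold in
R^768, and an unpruned tree ensemble can *memorize* that manifold at low
noise, classifying raw time windows well above chance.  The
time-vs-frequency contrast is therefore stated with the linear softmax
probe, for which the chance-level claim is exact.

**Fixture files** use the whitespace-delimited plain-text dialect
(`X_<split>.txt`, `y_<split>.txt`, `Inertial Signals/<channel>_<split>.txt`)
at `%.8e` (9 significant digits), so write→read round trips agree within
1e−7.

## Numerical and design notes

* Seeding: every stochastic component (fold partitions, forest seeds,
  generator draws) derives from explicit integer seeds through
  `numpy.random.SeedSequence`; derived seeds stay below 2³¹.  Identical
  data + config ⇒ bit-identical models and predictions.
* Model files are version-tagged pickle containers; loading a truncated,
  foreign, or version-mismatched file raises an explicit error, and a
  reloaded model predicts bit-identically.
* Degenerate inputs: singleton/pure tree nodes become leaves; a
  zero-iteration softmax or zero-round booster predicts the uniform
  distribution; empty tables, ragged text rows, out-of-range labels and
  mismatched dimensions raise typed errors naming the offending file and
  line where applicable.
* Problem sizes in the shipped experiments are desk-scale choices: the
  stacking comparison uses n_train = 2000, n_test = 1000, d = 24, NC = 6
  over 5 seeds with 100-tree forests and the 30-round booster, and the
  structural suites use a few hundred samples with small learners.
  Forest size enters the cascade and single-learner arms identically, so
  the cascade-vs-member comparison is unaffected by the scaling.

## Known limitations

* The literal k−1 augmentation averages partly in-sample predictions;
  with strongly memorizing members the layer CV accuracy saturates early
  and depth selection tends to pick shallow cascades.  Out-of-fold mode
  avoids this at the cost of noisier vectors.
* The from-scratch booster is exact and single-threaded; it is intended
  for thousands of samples and tens of features, not millions.
* Multi-grained scanning (sliding-window re-representation feeding the
  cascade) is not implemented.
* Real-dataset accuracies depend on the public benchmark files, which
  are not bundled; the package's empirical claims are those its tests
  and acceptance script compute on synthetic data and published count
  tables.
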