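# celearn — cascade ensemble learning for activity recognition

`celearn` implements a cascade ensemble classifier for human activity
recognition (HAR) from smartphone inertial sensors: given fixed-length
windows of triaxial accelerometer and gyroscope streams (128 samples at
50 Hz per channel), classify each window as one of a small set of
activities (walking, walking upstairs/downstairs, sitting, standing,
lying, ...).  It is aimed at researchers who want a deep-forest-style
stacking ensemble that trains on a CPU in minutes, with no feature
backpropagation and few hyper-parameters.

## The model

Each cascade layer holds four heterogeneous probabilistic classifiers:

* **XGB-style boosted trees** — written from scratch: each round takes a
  second-order Taylor expansion of the multiclass softmax loss, giving
  per-sample statistics `g_i = p_i − y_i`, `h_i = p_i(1 − p_i)`; one tree
  per class is grown greedily by exact split enumeration with gain
  `½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)] − γ`
  and leaf scores `w* = −G/(H+λ)`.
* **Random forest** (`gini_bagged`) — bootstrap resamples, Gini-optimal
  splits over √d candidate features.
* **Completely-random forest** (`fully_random`) — full sample per tree,
  one uniformly random candidate feature per split.
* **Softmax regression** — from scratch: multinomial logistic model
  `p(y=k|x) ∝ exp(w_kᵀx)` fit by full-batch gradient ascent on the
  L2-penalized mean log-likelihood.

For every training sample each classifier emits a *class vector* — its
estimated probability distribution over the NC classes — via seeded
k-fold cross validation (default: the average of the k−1 fold models that
trained on the sample; classic out-of-fold stacking is available too).
The four class vectors (4·NC columns; 24 for six activities) are
concatenated with the original features and fed to the next layer, so
every layer past the first consumes a constant width d + 4·NC.  A layer's
accuracy is the fused (mean of the four matrices, argmax) CV prediction
against the training labels; training stops once that accuracy has gone
`patience` (default 3) consecutive layers without improving, and
prediction fuses at the best layer.

Raw windows can be used directly through the **FFT path**: per channel,
the magnitude of the unnormalized DFT (all 128 bins kept, so a 6×128
window maps to exactly 768 features).  Because `|DFT|` is invariant to
circular time shifts, these features are unaffected by where a periodic
movement falls inside its window.

Evaluation uses a paired count/percentage confusion report: an
(NC+1)×(NC+1) table whose inner cells pair each count with its share of
the test set, bordered by per-predicted-class precision, per-true-class
recall, and the overall accuracy/error corner.

## Worked example

```sh
python examples/02_train_cascade.py
```

```
train: 900 x 24, 6 classes
layer 1: cv accuracy 99.78%
layer 2: cv accuracy 100.00%  <- best
layer 3: cv accuracy 100.00%
layer 4: cv accuracy 100.00%
layer 5: cv accuracy 100.00%
depth selected automatically: 2 (stopped after 5 layers; patience 3)
every layer past the first consumed 24 + 4 x 6 = 48 features
held-out test accuracy: 90.67% on 450 samples
```

The per-layer figures are fused cross-validated accuracies on the
training set; the plateau after layer 2 triggers the patience rule, and
prediction propagates through layers 1–2 only.  The held-out figure is
honest test accuracy on fresh samples from the same generator.
`examples/01_fft_features.py` shows the FFT path (raw time samples ≈
chance for a linear model, FFT magnitudes ≈ 100%), and
`examples/03_confusion_report.py` renders the full confusion report for a
published benchmark count table (overall accuracy 96.88%, walking
precision 94.98%, walking recall 99.19%).

A thin CLI wraps the same library calls:

```sh
celearn train --mode handcrafted --x X_train.txt --y y_train.txt \
              --seed 0 --out model.bin
celearn evaluate --model model.bin --x X_test.txt --y y_test.txt
celearn ablation --x X_train.txt --y y_train.txt \
                 --test-x X_test.txt --test-y y_test.txt --repeats 10
```

`train` writes a JSON run manifest (config, seeds, versions, per-layer
accuracies) next to the model; `ablation` reports mean ± sd test accuracy
for each single classifier and the named cascade combinations.

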