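# Methods

This note documents the models, estimators, defaults, and design choices
implemented in `relnose`, and what the synthetic experiments do and do not
demonstrate.

## Preprocessing

Two acquisition regimes are reduced to a common `[240, 8]` sample shape:

- **meta-training regime** (long wind-tunnel-style recordings, 40,000
  points at 10 ms): rows are averaged per second (100 raw points → 1 row,
  giving `[400, 8]`), then truncated to the 0-based half-open per-second
  window `[17, 257)`, which contains the informative rise/plateau/decay
  segment and has exactly 240 rows. The window is half-open by
  construction: a closed interval would give 241 rows and break the shape
  contract downstream.
- **meta-testing regime** (short breath recordings, 4,000 points over
  8 s): equal time-interval extraction keeps rows
  `round(i · (n−1)/(target−1))`, endpoints included,
  round-half-to-even.

Normalization is per-sample, per-channel min–max to `[0, 1]`. Per-sample
scaling means no statistic of the test set ever leaks into training; the
price is that absolute response amplitude is discarded, so class identity
must be carried by curve *shape* (onset, kinetics, relative channel
behaviour). A constant channel maps to 0 by convention. Recordings with
any missing or non-numeric cell are discarded whole, never imputed: a
partially recorded acquisition is evidence of a failed run, not missing
data at random.

**Channel shuffling** is the training augmentation: one random permutation
of the sensor columns per episode, applied identically to every support
and query sample of that episode. Per-sample permutations would destroy
the cross-sample channel correspondence that similarity scoring depends
on; a per-episode permutation only removes the model's dependence on a
fixed channel order. It is applied during training only.

## Sensor ranking

Each sensor contributes two scalar features per recording: the temporal
mean response and the maximum absolute first difference of the per-second
(preprocessed) series. Features are discretized by equal-width histogram
binning (default 20 bins, edges over the full feature vector — the
standard global plug-in estimator), and scored with the empirical mutual
information in nats, `0·log 0 := 0`. The combined sensor score is the
arithmetic mean of the two feature MIs; ranking is by descending combined
score with ties broken toward the lower sensor id. Natural logarithm is
the default base and is what the worked values in the tests assume.
Continuous (k-NN) MI estimators and joint multi-sensor selection are out
of scope.

## Episodes

An N-way K-shot episode draws N classes (each needing at least K+1
samples), K support samples per class without replacement, and up to P
query samples per class disjoint from the support set; small classes are
clipped rather than rejected, so an 8-sample class can still appear in a
4-shot episode with 4 queries. Default P = 20 queries per class. Episode
draws, parameter initialization, augmentation, and dropout all descend
from one seed via independent generator streams, making a training run a
pure function of its config.

## Networks

All models share the embedding `f_φ`:

stem `Conv(8→30, k=3, same)` → leaky-ReLU → average pool (k=3, stride 3;
240 → 80 steps) → 3 residual blocks → `Conv(30→30, k=18, valid)` →
leaky-ReLU, yielding `[30, 63]` (channels × steps) per sample. Each
residual block is `y = F1(x) + F2(x)` with F1 = three `k=3` same-padded
convolutions (batch norm + leaky-ReLU, slope 0.01) followed by an SE
block, and F2 a single `k=1` convolution. Blocks preserve shape, so the
`[63, 30]` output contract holds for any block count (2–6 are tested).
The pooling sits directly after the stem rather than at the end: the
blocks then operate on 80-step maps at identical expressiveness per the
shape contract and one third of the cost. The construction asserts the
contract at startup with a dummy forward pass.

The **SE block** squeezes each channel to its temporal mean, passes the
channel vector through a bottleneck of two fully connected layers (width
`ceil(C/ratio)` with ReLU, back to C with sigmoid; default ratio 16), and
rescales each channel by its (0, 1) weight.

The **relation head** concatenates the class feature map (mean of K
support embeddings — so K identical supports reduce exactly to the 1-shot
score) with the query map along channels (`[60, 63]`), then applies
`Conv(60→30, k=3, same)` + batch norm + leaky-ReLU → SE block → a
single-hidden-layer bidirectional GRU (32 units per direction; the
concatenated final forward/backward states feed onward) → dropout 0.3 →
`Linear(64→1)` → sigmoid. The GRU follows the standard reset/update-gate
recursion with sigmoid gates and tanh candidate; both directions are also
available fused as a single tape primitive whose
backpropagation-through-time is written out explicitly (the test suite
checks it against the per-step recursion). Ablation variants — stacked
BiGRU layers, unidirectional GRU, (Bi)LSTM, plain RNN — are selectable
via `HeadConfig.recurrent` / `num_layers`.

The **Siamese baseline** flattens embeddings (1890-vectors), takes the
elementwise absolute difference between the class-mean and the query, and
maps it through `Linear(1890→64)` + ReLU + dropout + `Linear(64→1)` +
sigmoid. The **prototypical baseline** uses class-mean flattened
embeddings as prototypes and a softmax over negative squared Euclidean
distances; it has no trainable head beyond the embedding.

Prediction is the argmax over class scores; ties resolve to the lowest
class index.

## Training and evaluation

One training epoch = one episode: sample, shuffle channels, compute the
loss (summed squared error against the 0/1 relation targets for the
relation and Siamese heads; negative log-likelihood for the prototypical
head), and take one Adam step. Default learning rates: 1e-4 for the
relation and Siamese models, 1e-5 for the prototypical model; default
schedule 1001 epochs with a 50-episode test every 20 epochs. Records
between epochs 700 and 1000 (inclusive; 16 records at the default
cadence) aggregate into means and 95% t-interval half-widths
`h = (σ/√n)·t_{0.975, n−1}` with σ the sample (n−1) standard deviation.
A test pools its episodes' predictions into one confusion matrix (rows =
predicted, columns = reference) per test; per-episode averaging is
available as an option. F1 is macro-averaged by default because the
breath-panel class sizes are strongly imbalanced (40/8/20/10); micro and
weighted averaging are options. Non-finite loss aborts with a diagnostic
rather than continuing silently.

Numerics: tensors are float64 by default; training runs compute in
float32 (`TrainConfig.dtype`), which changes no behavioural guarantee and
roughly halves runtime. Every numerical-equivalence test (gate
recursions, oracle comparisons, K-shot collapse) runs under float64.

## Synthetic data generator

The generator emulates the statistical structure of sensor-array
datasets with first-order kinetics: baseline → exponential rise toward a
class/sensor-specific plateau after gas onset → exponential decay after
gas-off, plus white Gaussian noise, optional linear drift, and per-sample
amplitude/baseline jitter (default 5%) so samples within a class are
similar but not identical. A class signature comprises per-sensor
amplitudes, rise/decay time constants, and onset delays; the
`separation` parameter scales every between-class difference (0 collapses
all classes onto one profile), and since normalization removes per-channel
amplitude, class identity is deliberately carried by kinetic and onset
differences as well. Presets mirror the two regimes: `metatrain`
(40,000 points, gas on from 20 s to 200 s, default 11 classes) and
`metatest` (4,000 points over 8 s, class sizes 40/8/20/10). Defaults:
noise SD 0.02 (≈2% of a unit plateau), separation 1.0, baseline 0.1.

What it does *not* model: wind-tunnel turbulence, sensor drift and aging,
humidity/temperature confounds, inter-device variation, or the
within-class biological variability of real breath. Passing the synthetic
few-shot recovery test therefore demonstrates that the pipeline can learn
and transfer a similarity function under controlled, well-separated
conditions — it is not a claim about accuracy on real breath data.

## Scaled-down experiment sizes

The packaged experiments are sized for a single CPU: the few-shot recovery
check trains a relation model for 300 episodes (learning rate 1e-3 — a
larger step size than the 1e-4 of the full 1001-epoch schedule, chosen for
the shorter budget) on a 6-class meta-training bundle of 25 samples per
class with separation 2.0 and noise 0.02, with 10 queries per class, and
evaluates on the disjoint 40/8/20/10 meta-testing bundle. Under these
conditions pooled 4-way 1-shot accuracy crosses 0.90 well before the
episode budget, and 4-shot evaluation is at least as accurate as 1-shot
up to a small tolerance.

## Known limitations

- The convolution widths/kernels inside the metrics head and the BiGRU
  width are package defaults, config-exposed but not externally fixed.
- The MI estimator is the plug-in histogram estimator; it is biased
  upward for small samples (all comparisons in-package use the same
  estimator, so rankings are consistent).
- Checkpoints store parameters by attribute path; architectural renames
  invalidate old checkpoints.
- The autodiff engine implements exactly the operator set these models
  need; it is not a general-purpose framework.
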