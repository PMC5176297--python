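# Methods

## Model

The meta-predictor treats the outputs of M base pre-miRNA classifiers as
an M-dimensional feature vector per RNA hairpin and learns a mapping to
the class label (+1 genuine precursor, −1 pseudo-hairpin) with a single
hidden-layer logistic network. The pipeline has three fitted stages —
numericalization/scaling, optional log-shift with sentinels, optional
PCA rotation — followed by the network. All fitted state (scaling
bounds, sentinels, eigenvectors, weights) is estimated on training data
only and applied frozen to held-out data.

### Score dialects

Each input column is governed by a `PredictorSpec`: binary columns carry
a positive token and a set of negative tokens; numeric columns carry
finite reals plus, where the dialect allows it, the literal `NA`.
Binarized ±1 calls (used for the evaluation and agreement analyses, not
for the meta-learner) apply each dialect's own positive range: a numeric
cell is a positive call iff it reaches the dialect's smallest positive
score (50 for MiPred-like, 0.8 for miRPara-like, 0.017 for ProMiR-like);
`NA` is always a negative call.

### Preprocessing

* **Mode I.** Tokens → ±1. Numeric columns are affinely mapped so the
  training minimum → −1 and maximum → +1. The closed interval [−1, 1]
  is attained at the training extremes by construction. `NA` in a
  numeric column is pooled with the raw value 0 (the dialect's negative
  score) before scaling, keeping mode I a pure numericalize-and-scale
  step.
* **Mode II.** For designated heavy-tailed columns (by default those
  whose dialect admits `NA`): `NA` → −30, exact 0 → −25, positive
  x → ln x, then min–max scaling as in mode I. Natural log is used: it
  places the smallest dialect score (1e-10 → −23.03) strictly above the
  0-sentinel, so the ordering NA < 0 < genuine scores survives the
  transform; the fit refuses data that would break this ordering. The
  sentinel values are fixed constants of the method (configurable per
  column). A negative raw value in a log column is a domain error.
* **Mode III.** Mode II, then Y′ = (Y − ȳ)·E where E holds the unit
  eigenvectors of the covariance (not correlation — mode II already puts
  columns on comparable [−1, 1] scales) of the training-fold features,
  ordered by descending eigenvalue. Signs are fixed so each
  eigenvector's largest-magnitude entry (first such entry on ties) is
  positive, and eigenvalue ties keep the symmetric-eigensolver order,
  making the rotation platform-deterministic. PCA requires N > M rows
  and non-zero total variance.

Degenerate cases: a constant numeric column maps to 0 everywhere and is
flagged; at apply time, numeric values outside the fitted range are
clipped to [−1, 1] so the network's input domain stays closed (binary
columns have no fitted state and always map to ±1).

### The network

Topology M → H → 1 with logistic activations everywhere; outputs
≥ 0.5 are positive calls. Defaults follow the published architecture
where one exists: H = 20 (5–60 is the explored range, enforced only as a
warning), 100-epoch early-stopping patience, 0.5 threshold. Choices the
source leaves open are plain configuration: per-sample (shuffled)
gradient descent with fixed learning rate 0.1; loss ½(y − t)² against
{0, 1} targets (log-loss available); weights i.i.d. uniform on
[−0.5, 0.5] with zero biases; epoch cap 500. Targets map +1 → 1, −1 → 0.

Early stopping monitors accuracy on a held-out test fold after each
epoch and stops once the running maximum has not been exceeded for
`patience` consecutive epochs; the returned model is the snapshot from
the best epoch, earliest on ties — the conservative reading of
"monitor the test accuracy". Consequence worth knowing: on very small
test folds that saturate at 100% within a few epochs, the snapshot
freezes early and may underfit relative to the final weights; this is
visible in unit tests with folds of ~6 samples and is negligible at
realistic fold sizes.

### Cross-validation

Stratified k-fold (k ≥ 3): samples are shuffled within each class with
the run's seed and dealt round-robin, so per-fold class counts are
within 1 of ideal. Rotation r validates on fold r, early-stops on fold
(r+1) mod k — a fixed rotation keeps runs deterministic where the source
says only "another subset" — and trains on the rest. Transforms and PCA
are refitted per rotation on the training fold(s) only; the network is
reinitialized per rotation with a seed derived from the master seed via
`SeedSequence([seed, rotation])`. All four metrics are averaged over
rotations identically and reported with standard error SD(n−1)/√k.
Whether the original study fitted normalization bounds and E per fold or
on the whole dataset is not stated; per-fold fitting was chosen because
whole-dataset fitting leaks validation information.

### Evaluation and agreement

SENS, SPEC, ACC, MCC follow the classical formulas; MCC is defined as 0
when a marginal sum vanishes; metrics are undefined (an error) without
both classes. Percentages print at 1 decimal and MCC at 2, matching the
field's tables, with raw values always retained. Pairwise agreement on
one class side counts T_i (true calls), O_ij (both true) and
U_ij = T_i + T_j − O_ij (at least one true); coverage ceilings
U_pos/P, U_neg/N and (U_pos+U_neg)/(P+N) bound any combiner of a pair.

### Duplicate filter

Samples with identical raw prediction vectors *and* identical labels
are duplicates; one survivor per group is chosen by a seeded uniform
draw (groups visited in first-occurrence order) and row order is
preserved. Raw cells, not binarized calls, are compared — the strictest
reading. The label is part of the key deliberately: collapsing a
positive and a negative with identical predictions would silently
change class balance.

## Synthetic panels

The generator stands in for the real benchmarks plus live runs of five
external tools, which are out of scope. It emulates each tool's output
dialect exactly (token vocabularies; MiPred-like positives uniform on
50–91; miRPara-like on 0.8–1; ProMiR-like positives log-uniform on
0.017–3240 and negatives a 0.5/0.25/0.25 mixture of log-uniform
1e-10–1e-2, exact 0, and `NA` — the published material gives shapes,
not weights, so the mixture weights are configurable defaults).

Two error models:

* **Latent difficulty.** Per sample, u ~ U(0,1) shared across
  predictors; predictor p is correct with probability
  clamp(base + ρ·(0.5 − u)) where base is its sensitivity or
  specificity. ρ = 0 gives independent errors; larger ρ correlates
  them. ρ is a qualitative knob, not an estimate of the real tools'
  dependence.
* **Complementary blind spots.** Each of five predictors errs on its
  own disjoint ~15% slice of positives and of negatives: individual
  accuracies ≈ 0.85 while any pair's coverage ceiling is 1.0 — the
  regime in which meta-prediction provably has headroom, with ground
  truth known by construction.

What a green test on synthetic panels does establish: the pipeline
recovers the combinable signal its inputs contain, respects the stated
dialects, and is bit-reproducible. What it does not establish: the
published cross-validated accuracies of the real meta-predictor, which
depend on the real datasets and the real tools' error structure; those
quantities are represented only by the printed confusion and agreement
counts, which the evaluation module reproduces exactly.

## Numerical choices

* Logistic function computed with inputs clipped to ±500 (exact in the
  operating range, overflow-safe outside it).
* Min–max scaling uses exact training extremes; equality of extremes
  flags the column constant rather than dividing by zero.
* Eigen-decomposition via the symmetric solver on the explicit
  covariance (M is small); tie-breaks as above.
* All randomness flows from `numpy.random.default_rng` seeded
  explicitly; derived seeds stay below 2³¹.

## Known limitations

* The per-sample SGD trainer is deliberately simple (no momentum,
  mini-batching, or regularization); wide networks on large panels
  train in seconds, not milliseconds.
* Mode I genuinely cannot separate heavy-tailed dialects whose positive
  and negative ranges nearly touch after min–max scaling (ProMiR's
  0.017 vs 1e-2) — that is the phenomenon mode II exists to fix, and
  tests assert perfect noiseless recovery only for mode II/III.
* The agreement analysis assumes call vectors aligned on a common
  sample set; it does not model tools that abstain on a subset.
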