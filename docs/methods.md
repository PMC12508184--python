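# Methods

## Problem setting

The package classifies individuals into ordinal multi-class health-risk
bands (canonically seven obesity classes, from insufficient weight to
obesity type III) from a mixed table of demographic, behavioral and
lifestyle features.  Three stages are chained: preprocessing, wrapper
feature selection, and an ensemble prediction stage.  Every stage is
re-fitted inside each cross-validation training fold, so no statistic —
imputation mean, outlier fence, normalization bound, selected feature, or
model weight — ever sees test rows.

## Preprocessing

* **Sparse-record removal.** A row is dropped iff its fraction of missing
  feature cells is *strictly* greater than `missing_row_threshold`
  (default 0.25).  Exactly 25% missing is kept.
* **Imputation.** Continuous gaps take the mean of observed values sharing
  the row's class label; a class with no observed values falls back to the
  global column mean (logged).  Categorical gaps take the column mode.  At
  inference time, where labels may be absent, the statistics learned at fit
  time are applied (class means when the held-out rows carry labels, global
  means otherwise).
* **Encoding.** Categorical levels map to integers via per-column maps
  (female=0/male=1; no=0/yes=1 flags; no/sometimes/frequently/always =
  0..3; walking..automobile = 0..4; the 7 obesity classes 0..6).  Encoding
  is idempotent and unknown levels are hard errors naming column and level.
* **Outliers.** Tukey fences per continuous column,
  `[Q1 − k·IQR, Q3 + k·IQR]` with `k = 1.5`.  Quartiles use linear
  interpolation between order statistics (the common spreadsheet
  convention; the convention is configurable and all tests assume linear).
  Default policy removes offending rows; winsorizing to the violated fence
  is available (`outlier_policy="clip"`).  Fences are fitted on training
  rows only and are never re-estimated on held-out data.
* **Normalization.** Per-column min-max to [0, 1] on training rows;
  held-out values may fall outside [0, 1] and are counted, not clipped
  (clipping configurable).  Constant columns map to 0 with a warning.

## Wrapper fitness

A candidate feature mask x is scored by
`Fitness(x) = w·Error(x) + (1 − w)·|x|/d` with `w = 0.99`.  `Error(x)` is
the misclassification rate of a k-nearest-neighbor classifier (`k = 5`,
Euclidean distance on the masked, normalized columns) on a stratified 30%
hold-out split drawn once per optimizer run and frozen, so fitness is a
pure function of the mask within a run and can be cached by mask bits.
Tie-breaks are pinned for exact reproducibility: equal neighbor distances
resolve to the lower training-row index, vote ties to the smallest class
label.  The empty mask is scored `Error := 1`, i.e. fitness `w`, so the
optimizer never stalls on a degenerate subset.  `w = 0.99` makes the error
term dominant; the size penalty (0.000625 per feature at d = 16) separates
only (near-)error-ties, which is exactly what lets the selector drop
redundant near-copies of informative features.

The k for the wrapper k-NN is a package default (5); the prediction-stage
k-NN base model independently uses 10 neighbors.

## The optimizer

A population of N = 30 bats, each carrying a real position/velocity vector
and a binary mask, runs for T_max = 50 iterations (defaults; the oracle
experiments use 100).  Per iteration:

1. **Entropy state.** Fitnesses map to selection probabilities by
   softmax(−F); their Shannon entropy H (bits), normalized by log2(N),
   gives `H_norm ∈ [0, 1]`.  With fitnesses in [0, 1] the softmax is
   near-uniform and H_norm sits close to 1 for most of a run — the
   entropy signal chiefly distinguishes collapsed swarms (H_norm → 0)
   from everything else.
2. **Parameter adaptation** (entropy-controlled variant): every bat gets
   `f = f_min + H_norm (f_max − f_min)` (band [0, 2]),
   `A ← A (1 − H_norm)`, and `r ← r (1 − e^{−γ H_norm t})` with γ = 0.9,
   t counting from 1.  The pulse rate is floored at r_min = 0.01 so local
   search never fully disables.  The classic variant (ablations) draws
   `f = f_min + (f_max − f_min)β`, β ~ U(0,1), and reschedules A (decay
   α = 0.9) and r only on candidate acceptance.
3. **Flight.** `V ← V + (x − x_g) f`, clamped to ±6, then `x' = x + V`.
   The clamp is standard binary-swarm practice: it keeps the sigmoid
   transfer responsive instead of saturating irreversibly.
4. **Local search**, triggered when a uniform draw exceeds the bat's pulse
   rate: the quantum jump `x' = x_g + θ (x − x_g) ln(1/u)` with θ = 0.75
   and one u ~ U[1e−12, 1] shared across dimensions per bat (the
   per-bat/per-dimension choice is an open design point; per-bat was
   chosen).  The ablation without the quantum flag uses the classic random
   walk `x' = x + ε·Ā`, ε ~ U(−1, 1), Ā the swarm's mean loudness.
5. **Transfer.** The candidate's bits are drawn through the stochastic
   sigmoid `P(bit_j = 1) = 1/(1 + e^{−x'_j})`.
6. **Evaluation and elitism.** The candidate is evaluated; the global best
   tracks the minimum over *every* evaluated candidate.  The classic
   acceptance test (uniform draw < loudness AND candidate beats the global
   best) gates the classic-variant A/r schedule.

**Saturated mask anchoring.** After each evaluation a bat's real position
snaps to ±c per bit of its evaluated mask (c = `saturation` = 2.5), and
the global best's position is likewise the saturated encoding of the best
mask.  This is the package's key numerical design choice: with positions
on the ±c lattice the sigmoid transfer reproduces a mask with per-bit
fidelity 1 − σ(−c) ≈ 0.92, so the quantum jump behaves as a guided
recombination whose flips concentrate on the coordinates where bat and
best disagree — a genuine local search in Hamming space.  Without the
anchoring, positions initialized in [0, 1] give per-bit probabilities of
0.5–0.73 and every "local" candidate is a near-random mask; the search
then plateaus far above the enumerable optimum.  c trades exploration
against exploitation (larger c → sharper reproduction, fewer flips); 2.5
gives an expected ~1.2 bit flips per fully-converged candidate at d = 16.

**Randomness.** One seed spawns independent sub-streams per bat index plus
a miscellaneous stream, so runs are bit-reproducible and robust to
iteration-order refactors.

## Prediction stage

Seven base classifiers are trained on the selected columns: logistic
regression (lbfgs), LightGBM (100 trees, learning rate 0.05), XGBoost
(depth 6, 100 trees, learning rate 0.01), AdaBoost (100 estimators,
learning rate 0.01), an MLP ((100, 50) hidden units, relu, adam, initial
learning rate 0.001), k-NN (10 Minkowski neighbors), and an RBF SVM
(C = 2, gamma = "auto").  A stratified 20% validation split provides
per-model accuracies; the fitted models from the 80% split are kept (no
refit on the full table, so the recorded accuracies describe exactly the
deployed models).  Prediction is the plurality class of the seven hard
votes; a tie among top classes resolves to the vote of the most accurate
base model among those voting for a tied class.  Soft (probability)
voting is deliberately not offered.

The optional hyperparameter search is a simplified tree-structured Parzen
estimator: trials split at the γ_tpe = 0.25 score quantile into good/bad
groups; one-dimensional Parzen densities l(x) and g(x) (mixture-of-normals
for continuous/integer ranges with bandwidth span/(4√n), smoothed counts
for choices) are fitted per hyperparameter; candidates sampled mostly
around the good group are ranked by Σ log l − log g and the best is
evaluated.  The full multivariate TPE is out of scope; the default
pipeline runs the fixed hyperparameters above and is fully deterministic.

## Evaluation protocol

One-vs-rest TP/TN/FP/FN per class feed
precision TP/(TP+FP), sensitivity TP/(TP+FN),
accuracy (TP+TN)/(TP+TN+FP+FN) and F = 2PR/(P+R), with 0/0 := 0
(warned).  Multi-class aggregation is macro (unweighted mean) by default;
micro and support-weighted variants are flags.  The fold report's headline
accuracy is the overall fraction correct.  Cross-validation uses 10
stratified shuffled folds (seeded); classes smaller than the fold count
trigger a warned fallback to unstratified folds.

## Synthetic study data

The generator plants a known ground truth to make selection quality
measurable.  Relevant features are i.i.d. standard normal; a fixed linear
score over them (coefficients cycling 1.0, −0.8, 0.6, −0.5, …, a
BMI-like weighted sum) is banded at its empirical quantiles into n_classes
ordinal labels, so labels are a deterministic function of the relevant
columns only and the class balance is exact by construction.  Redundant
features are affine copies of relevant ones at correlation 0.9 — good
enough substitutes that only the size penalty plus small error differences
remove them.  Noise features are independent normals.  Missing cells and
outliers (displaced a stated number of SDs beyond the observed extremes)
are injected with exact counts and an alteration log.  The default spec —
600 rows, 4 relevant + 4 redundant + 8 noise features, 7 balanced classes
— is the package's standard test bed.

The banded-score label rule makes k-NN informative but imperfect (the
bands are thin slabs in feature space), which is intentional: selection
must act on a noisy error signal, as it would on real data.  What the
generator does *not* emulate: real marginal distributions and categorical
lifestyle features of obesity cohorts, label noise, feature
interactions beyond linear scoring, and class imbalance (available via
`class_balance` but not default).  Passing recovery tests therefore shows
the selector handles redundancy/noise structure at realistic sample sizes,
not that it reproduces any particular cohort's numbers.

A separate fixture (`kaggle_schema_fixture`) emits the exact 16-column
obesity schema with string categorical levels and BMI-consistent labels,
purely for preprocessing round-trip tests; it is synthetic and not fitted
to any real dataset's marginals.

## Verification

The test suite checks, among others: exact hand-derived cases (quartile
fences on [1..8, 100]; softmax entropy of fitnesses (0, ln 3) = 0.8113
bits; the confusion-count arithmetic 0.75/0.75/0.8/0.75), determinism of
every seeded component, elitist monotonicity and entropy bounds along
optimizer traces, equivalence of the flags-off configuration with an
independent plain binary-BA reference under a shared RNG stream, a
leakage test that plants a test-fold-only outlier and verifies the fitted
fences ignore it, and four scaled-down study-level properties: the
optimizer attains the exhaustively enumerated optimum of a 10-feature
problem in ≥ 80% of 20 seeded runs; the median Jaccard overlap between
selected and planted features over 20 seeds is ≥ 0.6; the full algorithm's
final fitness is no worse than plain binary BA's in ≥ 70% of 30 paired
seeds; and two full pipeline runs under one seed agree bit-for-bit on the
selected mask and fold assignment.  Study sizes in these checks (300–600
rows, 10–16 features) are the package's chosen desk-scale conditions.

## Known limitations

* The entropy signal saturates near 1 for fitness spreads ≪ 1; the
  loudness consequently collapses after the first adaptation, and the
  entropy-controlled acceptance path rarely fires.  The algorithm's power
  on binary problems comes mainly from the elitist quantum local search;
  the ablation gap (full vs plain BA ≈ 0.48 vs 0.58 mean final fitness on
  the test bed) quantifies this.
* The pulse-rate decay multiplies r toward its floor, the opposite of the
  classic growth schedule; it is implemented as specified, with the floor
  preventing local-search shutdown.
* Wrapper selection inherits the hold-out split's noise (1/180 error
  quantization at the default sizes); masks within one misclassification
  of each other are separated only by the size penalty.
* The simplified TPE factorizes densities per hyperparameter and cannot
  model interactions between them.
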