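# Methods

## Profile model and score decoding

An HH-suite `.hhm` document describes a profile HMM over a query protein
of length L. Each residue block carries 20 match-emission scores in the
integer space `x = −1000·log₂ p`, with `*` denoting zero probability.
We decode scores with `f(x) = 2^(−x/1000)` and keep only the 20
residue-indexed emission columns (in the letter order of the file's `HMM`
header line, `A C D E F G H I K L M N P Q R S T V W Y`); the 10
transition/diversity columns are not residue-indexed and are discarded.
Decoded values lie in `[0, 1]`: `f(0) = 1` for a certain emission and
`*` maps to 0, the limit of `f` as `x → ∞`. Writing reverses the decode
with `round(−1000·log₂ h)`, so a parse → write → parse cycle reproduces
the matrix to within one integer-score quantum (relative error
≤ `1 − 2^(−1/1000)` ≈ 7·10⁻⁴ per cell) and is exactly idempotent from the
second cycle on.

Parsing is strict by default — a missing `#` separator or `//`
terminator, a residue block without exactly 20 emission fields, or a
`LENG` header disagreeing with the parsed block count abort with the line
number — because silent corruption of training matrices is worse than a
failed run. A lenient mode skips malformed blocks with a logged warning.

Profile construction itself (HHblits, four iterations, E-value 10⁻³
against a current UniProt) is external; a thin subprocess wrapper is
provided for convenience but nothing in the package or its tests depends
on it.

## Feature descriptors

Let `h_{i,j}` be the decoded matrix and `h̄_j` the mean of column `j`
over all L rows.

* AAC: `h̄_j`, j = 1..20.
* ACT: `A_{j,g} = (1/(L−g)) Σ_{i=1}^{L−g} (h_{i,j}−h̄_j)(h_{i+g,j}−h̄_j)`.
* CCT: `C_{j,k,g}` with the same form for ordered pairs `j ≠ k`.

Three conventions deserve note. First, `h̄_j` is always the full-column
mean (the AAC value), not the mean of the first `L−g` rows; the same
symbol denotes the same quantity in every family. Second, the normalizer
is `L−g`, not the unbiased `L−g−1`; the descriptor is a population-style
covariance, and we implement the stated form exactly. Third, the feature
layout is fixed and canonical — AAC by residue; ACT with residue outer,
lag inner; CCT with first residue outer, second residue inner (skipping
equal pairs), lag innermost — because selection results are communicated
as feature names (`AAC[A]`, `ACT[C,2]`, `CCT[A,C,1]`) and must mean the
same thing in every run. With all families the dimension is `20 + 400·G`;
the default `G = 5` (2020 dimensions) follows the observation that
accuracy is stable for lags around 5 and decays for larger G while the
dimension grows linearly, and it is overridable (1–10) for the lag sweep.

Profiles with `L ≤ G` are rejected rather than padded: the curated
benchmarks exclude sequences under 50 residues, so such inputs are
out-of-distribution and a hard error is the honest response.

## Feature ranking and selection

Features are ranked by tree-ensemble importance and the top K retained.
Two ensembles are supported with fixed, recorded hyperparameters
(500 trees; XGBoost additionally depth 6, learning rate 0.1,
single-threaded histogram method for determinism):

* **XGBoost** (default): *total gain* — the summed loss reduction over
  all splits using the feature. The per-split *average* gain exposed by
  some APIs over-rewards features split once with a lucky gain late in
  boosting, which measurably degrades recovery of planted signal;
  split-count ("weight") and average gain remain available by flag.
* **Random forest**: mean impurity decrease, normalized to sum 1.

Ties break by ascending original feature index, making every ranking a
deterministic total order. The default K = 270 follows the K-sweep
experiment shipped in the pipeline (K = 10, 20, …, 650 under CV).

Two ranking scopes exist. The historical protocol ranks once on the full
dataset and then cross-validates on the same data; this leaks label
information from fold test sets into the ranking and is optimistic. A
leakage-safe mode re-ranks inside each training fold. Both are
implemented; `rank_scope="full"` is the default to match the protocol
the benchmark numbers correspond to, and `"fold"` is recommended for any
new data — the label-permutation test in the suite verifies it stays at
chance on null data.

## Classification

The primary classifier is an RBF-kernel SVM. `C` and `γ` are tuned over
`(2^a, 2^b)` for integer exponents in `[−10, 10]` (441 candidates) by
stratified k-fold accuracy on the training data only, ties resolving
toward smaller `C` then smaller `γ` (simpler, smoother models). An
`exp_step` option coarsens the grid (step 2 → 121 candidates) for
budget-limited runs without changing the bounds. Features are
standardized with training-fold statistics before the SVM (constant
features get scale 1): AAC components live in `[0, 1]` while ACT/CCT
components are bounded by ±0.25 and typically are orders of magnitude
smaller, and the RBF kernel is scale-sensitive. A flag disables
standardization for ablation. The comparison classifier is a 500-tree
random forest; its score is the positive-class vote fraction, while SVM
scores are signed decision values.

Models serialize to a single joblib file embedding a schema version, the
feature-name contract, scaler statistics and hyperparameters; loading
across schema versions is refused, and prediction aligns columns by name
(any mismatch is an error naming the offending features).

## Evaluation

Protocols: stratified shuffled 10-fold CV (seeded), jackknife CV
(leave-one-out, its standard meaning in this literature), and an
independent test (single fit on the training set, single evaluation on a
disjoint test set). All CV metrics are computed from pooled held-out
predictions — each sample scored exactly once — rather than averaged per
fold; pooling is required for jackknife MCC/AUC to be defined at all.

Metrics: SN, SP, ACC, MCC (with the 0/0 denominator case defined as 0)
and AUC. AUC is the Mann–Whitney pair statistic computed from mid-ranks
(ties at half weight); the ROC curve is produced independently by
threshold sweep and the test suite requires the trapezoidal area to agree
with the pair statistic to 10⁻⁹.

## Synthetic data

The generator emulates the statistical structure the descriptors detect,
in the decoded `[0, 1]` space. Per run, baseline column means are drawn
once from `U(0.25, 0.6)` (columns are non-exchangeable, like amino-acid
composition bias); per protein, a per-column offset `N(0, 0.05)` and
residue-level noise `N(0, 0.08)` are added, and lengths are uniform on
[50, 300] by default (mirroring the benchmarks' length filter). The
default class sizes, 525 positives / 550 negatives, mirror the curated
training benchmark's shape.

The positive class additionally receives, all scaled by one
`effect_size` knob: a mean shift of `0.08·effect` on designated columns
(AAC signal); AR(1) noise with coefficient `min(0.35·effect, 0.95)` and
matched marginal variance on designated columns (lag-decaying ACT
signal); and a lagged partial copy with weight `min(0.5·effect, 1)`
between designated column pairs (CCT signal at the coupling lag). Values
are clipped to `[0, 1]` — simple and reproducible — and `effect_size = 0`
makes the class distributions exactly identical, which the null
calibration tests exploit. At `effect_size = 1` each planted AAC feature
carries a standardized two-class difference of roughly 1.2.

What passing tests on this generator do and do not show: they validate
the mechanics (formats, layouts, determinism), the statistical behaviour
(planted channels are recovered by the intended feature family; null data
stays at chance; selection improves accuracy when most dimensions are
noise), and the leakage properties of the protocols. They do not show
anything about real proteins — real HHblits profiles have heavy-tailed,
column-correlated score distributions this generator does not attempt to
mimic, and real class signal is far weaker and more distributed.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run everything at desk
scale as the package's own defaults for self-validation: synthetic
benchmarks of 60–300 proteins, the coarse (step-2) grid search with
5 folds where the full 441-candidate grid would add nothing to the check,
and jackknife restricted to ~100 samples (leave-one-out cost grows
linearly in models trained; the pipeline gates large-n jackknife behind
an explicit flag). All randomness flows from a single seed; fits are
single-threaded so rankings and fold splits are bit-reproducible.

## Known limitations

* Real `.hhm` profiles depend on the aligner version and sequence
  database; the same protein profiled against different UniProt releases
  yields different matrices, so published numbers tied to a specific
  database snapshot are not bit-reproducible from sequences alone.
* The ACT/CCT bound of ±0.25 holds asymptotically (`L ≫ g`, values in
  `[0, 1]`); for `L` close to `g` the normalizer `L−g` permits slightly
  larger magnitudes. With the enforced `L > G` and benchmark-scale
  lengths this is immaterial.
* Grid search optimizes accuracy only (matching the protocol the
  benchmarks report); class-imbalanced applications would want a
  different objective.
* No probability calibration, no kernels beyond RBF (a config escape
  hatch aside), no multi-class support.
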