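# Methods

## Problem setting and model

The package targets labeled expression-like matrices in the small-n,
large-m regime: n samples (tens to hundreds), m features (hundreds to tens of
thousands), c ≥ 2 classes. The method is a two-stage hybrid: a cheap
filter-based overall ranking of all m features, followed by an expensive
wrapper search restricted to that order. Nothing in the pipeline assumes a
particular platform; any non-negative-scalable numeric matrix works.

## Stage 1: filter scores and rank fusion

**Scaling.** Every column is min–max scaled onto [0, 1]:
x' = (x − min X)/(max X − min X). A constant column divides by zero; it is
mapped to all zeros — the feature is uninformative regardless, and 0 keeps the
value in range and non-negative (the chi-squared scorer requires
non-negativity). Scaling is idempotent and order-preserving, and is applied
exactly once, before all scoring.

**Chi-squared.** The statistic is defined on a contingency table; continuous
expression values have no natural levels, so the table rows must be
constructed. Two conventions are provided:

* `binned-contingency` (default): the feature is cut into `n_bins` equal-width
  bins on [0, 1] (default 10), counts form the observed table, the usual
  independence product gives the expected one, and empty bins are dropped
  (they carry neither observed nor expected mass; this avoids 0/0). This
  evaluates the textbook statistic literally and is cross-checked in the tests
  against scipy's Pearson chi-squared without continuity correction.
* `weighted-frequency`: per-class sums of the scaled values act as observed
  "frequencies", apportioned expectations come from class sample proportions —
  the convention of ML toolkits for real-valued non-negative features
  (cross-checked against scikit-learn's `chi2`). Provided for comparison
  experiments; the default is the literal table.

**F score.** For two classes the score is
[(x̄₊ − x̄)² + (x̄₋ − x̄)²] / [s₊² + s₋²] with unbiased class variances.
This is deliberately *not* the classical one-way ANOVA ratio (no group-size
weighting, no mean squares): its null mean is ≈ 1/n rather than ≈ 1. Since
only the induced rank order feeds the next stage, the scaling is immaterial
downstream. For c > 2 the standard one-way ANOVA F is used — the two-class
form does not generalize, and multi-class runs need *some* variance-ratio
score. Degenerate case: zero within-class variance with distinct class means
returns +inf, which ranks ahead of every finite score; zero numerator returns 0.

**Mutual information.** Plug-in histogram estimate in bits: the feature is cut
into `n_bins` equal-width bins on [0, 1] (same default 10), the empirical
joint with the class gives I(X;Y) = Σ p log₂ p/(p·p), 0·log 0 terms dropped.
The estimate is biased upward by ≈ (r−1)(c−1)/(2n ln 2) under independence;
with 10 bins, 2 classes and n = 100 that is ≈ 0.065 bits. No bias correction
is applied — ranks, not absolute values, matter.

**Ranks and moderation.** Each score column becomes ordinal ranks 1..m
(highest score → 1; ties broken by first occurrence, so every feature holds a
distinct rank and the result is deterministic; continuous scores essentially
never tie). Each rank triple (r₁, r₂, r₃) is then moderated: if the largest
entry strictly exceeds twice the sum of the other two it is replaced by
exactly twice that sum. At most one entry can trigger (two entries ≥ 1 cannot
each exceed twice a sum containing the other), the replacement value sits
exactly at the trigger threshold so one pass is a fixpoint, and moderation
never increases the row sum. The overall rank OR is the moderated row sum
(3 ≤ OR ≤ 3m); sorting ascending by OR gives the ORT.

**Tie-break.** Equal-OR features keep their pre-sort (original feature) order
— a stable sort. The published worked-example tables that ship with the
package order their equal-OR rows inconsistently with each other, so no
secondary key can match both; stable-by-input-order is the deterministic
choice, and only the OR values themselves are contractual.

## Stage 2: wrapper selection

**Evaluation.** A feature subset is scored by stratified k-fold
cross-validated accuracy (k = 10 by default; stratification because class
counts are small and unstratified folds can lose a class entirely; folds are
shuffled under an explicit seed). Inside each outer training set a grid
search over the classifier's hyperparameter grid picks the combination with
the best inner stratified 3-fold accuracy (ties: first grid point) — nested,
so the held-out fold never influences tuning. Accuracy generalizes to
multi-class as the fraction of correctly labeled cases.

**Default grids** (all overridable): SVM C ∈ {0.1, 1, 10, 100} ×
kernel ∈ {linear, rbf}; decision tree max_depth ∈ {3, 5, 10, none}; random
forest trees ∈ {100, 200} × max_depth ∈ {5, none}; KNN k ∈ {1, 3, 5, 7}.
A `custom` classifier slot accepts any fit/predict estimator, which also
enables fully deterministic mock evaluators in tests.

**Greedy loop.** The top-ORT feature is always retained and sets the baseline.
Each subsequent feature is appended, the subset re-evaluated (fresh grid
search and CV, same seed policy), and kept only on *strict* improvement —
"less than or equal" excludes, so ties never grow the subset. The loop visits
every ORT row once; there is no early stopping by default (an optional
`max_features` cap exists for budget control, and `tune_every_step=False`
tunes once on the top feature and reuses those hyperparameters for large-m
tractability). The trajectory (feature, accuracy, kept) is recorded for every
candidate, and the reported best accuracy always equals a re-evaluation of the
final subset under the same seed.

## Synthetic data

The generator emulates the regime the method is built for, not real platform
noise. Noise features are i.i.d. standard Gaussian. Informative feature j in
class k has mean `effect_size · sign_j · (k − (c−1)/2)` with unit variance:
evenly spaced class levels, so every class pair is separated by at least
`effect_size` noise standard deviations on every informative feature, with
`sign_j` alternating so both up- and down-shifted markers occur. Labels follow
the requested class proportions exactly to within one sample
(largest-remainder apportionment) and are shuffled; the matrix is min–max
scaled before return; everything derives from one seed.

Defaults — n = 100, m = 200, 5 informative features, 2 balanced classes,
effect size 2.0 — describe a small two-group expression study with a sparse,
moderately strong signal: large enough in m/n to be honest about the
dimensionality problem, small enough to evaluate exhaustively. What the model
deliberately omits: heteroscedastic platform noise, probe–probe correlation,
batch effects, heavy tails. Passing recovery tests on this generator
demonstrates the machinery is correct under the stated model, not that real
microarray panels will be recovered at these rates.

## Numerical and design choices

* Values exactly at 1.0 fall into the last histogram bin; values are clipped
  to [0, 1] before binning.
* Ordinal ranking uses first-occurrence tie-breaking throughout.
* Grid-search ties resolve to the first grid point; per-fold winning
  hyperparameters are aggregated by majority (first occurrence on ties).
* The +inf F sentinel ranks as the single best score.
* All randomness (fold shuffling, forests, the generator) flows from explicit
  integer seeds recorded in result objects and run manifests.
* Problem sizes in the test suite follow the defaults above; the oracle-
  equivalence suites run on small tables (m ≤ 10) where exhaustive references
  are trivially correct.

## Known limitations

* **Filter-stage selection bias.** The ranking is computed on the full
  dataset before cross-validation, per the method's own protocol. On pure
  noise, the top-ranked features are exactly those spuriously correlated with
  the labels in every fold, so even a single top-feature CV accuracy is
  optimistically biased; the greedy keep-on-improvement loop then takes a
  running maximum over hundreds of noisy CV estimates and inflates further.
  Measured on permuted-label data (n = 100, m = 200, KNN), the reported best
  accuracy reaches ≈ 0.70 where an unbiased null evaluation is ≈ 0.50. The
  reported best accuracy is therefore an *optimistic* estimate — for an
  unbiased error estimate, wrap the entire pipeline (ranking included) in an
  outer cross-validation loop on held-out data.
* The strict-improvement rule makes the selected subset sensitive to fold
  seeds near accuracy plateaus; the trajectory log exists to audit this.
* Equal-width binning is simple and deterministic but wasteful for skewed
  features; no adaptive binning is provided.
* No imputation, batch correction, or binary platform formats; inputs are
  complete delimited text matrices.
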