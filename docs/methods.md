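# Methods

This note documents the models, defaults and design choices behind
`chainfs`, and what the synthetic benchmark does and does not show.

## Filter stage

**Relevance (Kendall).** Feature relevance is |τ_b(F, L)| with labels
encoded as integers in sorted label order. τ_b is the tie-corrected form
(scipy's implementation; a brute-force pair-count oracle cross-checks it in
the test suite). Constant vectors get τ = 0 by convention rather than NaN —
a constant feature carries no ordering information, and NaN would poison the
greedy ranking. For more than two classes the integer encoding imposes an
ordinal reading of the label; rank correlation against a genuinely nominal
multi-class label is a known limitation, which is one reason ReliefF (which
handles nominal classes natively) runs second.

**Redundancy (chi-square).** Feature–feature association uses a Pearson
chi-square on equal-frequency discretizations (default 5 bins; duplicate
quantile edges are merged, so low-cardinality columns fall back to their
natural categories). The statistic is normalized by N·(min(r, c) − 1) —
squared Cramér's V — so redundancy lies in [0, 1] and is commensurate with
|τ|; without this the two terms of the greedy objective live on different
scales. A 2×2-specific form is also exposed with two modes: a
"literal" φ²-style quantity (xw − yz)²/∏margins and the textbook statistic
that multiplies it by the grand total; the literal form is the default for
the 2×2 helper, while the general binned redundancy uses the standard
Pearson statistic. Constant columns have redundancy 0; a zero margin makes
the 2×2 association degenerate and returns 0 with a warning.

**Greedy MKMC ranking.** The first pick maximizes relevance; each later
pick maximizes relevance − redundancy-to-selected, where the redundancy of
a candidate against the selected set is the **minimum** normalized
chi-square over its members by default (a "mean" aggregator is available and
is the usual mRMR choice). Ties break toward the lower feature index, which
makes rankings bit-reproducible. Scores are the true greedy objective
values; note that with the min aggregator the aggregate can shrink as the
selected set grows, so the score sequence is bounded by the first pick but
not necessarily monotone. The min aggregator also means an exact copy of an
already-selected feature is only fully penalized against that feature: its
*smallest* redundancy over the set governs. This is the intended
literal behaviour; use `aggregator="mean"` for the stricter standard form.

**ReliefF.** Standard multi-class ReliefF: m sampled instances (default:
every instance once, in seeded random order), k = 10 neighbours capped at
the smallest class size minus one, features min-max scaled before Manhattan
distances, misses weighted by P(C)/(1 − P(class(R))), all contributions
divided by m. Neighbour ties break by sample index. Weights of duplicated
columns are identical by construction.

## Wrapper stage (IGWO)

Positions live in [0, 1]^d and are clamped there after every update; the
update itself is the classic three-leader average with fresh per-wolf,
per-leader, per-coordinate coefficient draws. Deviations from classic GWO
and their defaults:

| parameter | default | meaning |
|---|---|---|
| pop_size | 30 | pack size (≥ 3; three leaders required) |
| max_iter T | 100 | iterations |
| a schedule | 2 − rand·2t/T | randomized convergence factor in [2 − 2t/T, 2] |
| perturbation start | t > ⌊2T/3⌋ | late-phase disturbance branch |
| Q | R·σ + mean per wolf | R = sin(rand·π·t/T); σ, mean over the wolf's own coordinates (1/s normalization) |
| threshold r | sin(rand·π)·e^(−t/T) | oscillatory binarization cutoff, one draw per iteration |
| w_f | sin(π/2·t/T) | accuracy weight in the scheduled fitness |

Specific choices where the design was open:

* **Length term.** The fitness uses 1 − LEN/d rather than raw subset
  length, so the two terms share the [0, 1] scale and smaller subsets score
  higher; adding raw length would reward complexity, the opposite of the
  dual-metric intent.
* **Q scales the averaged position**, not each leader contribution, and is
  one scalar per wolf.
* **Clamping** after every update keeps positions comparable with the
  binarization threshold; without bounds the multiplicative Q drifts
  positions outside [0, 1].
* **Empty masks** fall back to selecting the coordinate with the largest
  continuous value (lowest index on ties), so every evaluation sees at
  least one feature.
* **Leaders are re-ranked each iteration by current scheduled fitness**
  (non-elitist, classic GWO), while the best (mask, fitness) ever seen is
  recorded separately and returned. Because w_f changes with t, "best so
  far" compares fitness values whose accuracy/length mix differs across
  iterations; the record is monotone by construction.
* **Draw order** (one seeded generator): per iteration — threshold r, then
  a, then per wolf per leader the A and C vectors, then (late phase) one R
  per wolf. Fixing the seed reproduces runs bit for bit. Identical masks
  are evaluated once per run (cached); the evaluator is deterministic given
  its own seed, so caching does not change results.
* **Ablation.** `perturbation=False` with `random_a=False` reduces the
  optimizer exactly to vanilla binary GWO with the linear a schedule; the
  test suite verifies bit-for-bit agreement with an independent
  implementation.

## Evaluation

The accuracy oracle is stratified k-fold cross-validation (default 10
folds). Feature standardization and, for the default RBF-SVM, the grid
search over C ∈ {0.1, 1, 10, 100} and γ ∈ {10⁻³, 10⁻², 10⁻¹, 1} are fitted
on each training split only (the search uses an inner 3-fold loop); the
test fold is touched once, for scoring. Standardization is included because
RBF kernels need comparable feature scales. The classifier is injectable;
`"nearest-centroid"` gives a fast surrogate used in the wrapper search of
the test and acceptance runs, where thousands of subset evaluations make
per-mask grid search impractical. Repeated runs (default 10) re-seed both
the CV split and the optimizer, and report mean ACC, final LEN and
DRR = LEN/dim.

## Chain

Preprocessing imputes missing cells with the column mean of observed values
and replaces observed outliers (|z| > 3, computed on observed values) with
that same mean. The candidate rule keeps everything at dim ≤ 1000 and caps
S₁ at 100 above it. The stage-2 fraction defaults to 1.0 for dim ≤ 1000
(low-dimensional panels tolerate no aggressive cut before the wrapper) and
0.4 above (successive-cut regime); it is a config knob. The wolf pack
searches S₂ only — the funnel view of three strictly nested layers — and is
initialized uniformly at random over S₂'s coordinates, without bias from
the filter ordering. Repetition seeds derive as seed + run_index. The
literature sometimes labels datasets "high-dimensional" from 2000 features;
the algorithmic switch here is the candidate rule's 1000, and the label is
only nomenclature.

## Synthetic benchmark

The generator plants: informative features (class-conditional Gaussian mean
shift of `class_separation` within-class standard deviations, sign
alternating with class and feature index so every informative feature
separates classes), redundant features (a designated informative parent
plus Gaussian noise, default sd 0.1), and independent standard-normal noise
features. Classes are balanced; missing cells, when requested, are injected
completely at random with at least one observed value kept per column.
Defaults (200 samples, 5 informative at 3σ, 5 copies, 50 noise, 2 classes)
give a benchmark where filters should rank all signal features on top and
the wrapper should reach near-perfect accuracy with a handful of features.

What it does not emulate: heavy-tailed and count-valued expression
distributions, correlated noise blocks, batch effects, class imbalance, and
label noise. Passing recovery tests here shows the machinery is wired
correctly, not that the method will dominate on real microarray panels.

One behaviour worth understanding when interpreting recovery numbers: at 3σ
separation, two to three signal features already saturate cross-validated
accuracy, and the dual-metric fitness then prefers the *smallest* such
subset. The pipeline therefore returns compact masks (typically 2–6 of 60
features, accuracy ≈ 1.0) that cover the planted signal but deliberately do
not enumerate all of it, and noisy copies substitute freely for their
parents. Full recovery of every planted informative feature is not an
optimum of this objective and is not expected.

## Problem sizes and numerics

Test and acceptance runs use the planted 200×60 benchmark with pop 30 and
T = 50, the nearest-centroid evaluator, and 10 seeded repetitions; the
optimizer-level recovery check uses d = 20 with 3 planted features. Oracle
agreements are asserted to 10⁻¹² (position updates, rank correlation) and
10⁻⁹ (ReliefF vs a naive reference). Degenerate inputs are defined rather
than exceptional wherever a convention is defensible (constant features,
zero margins, empty masks); genuinely ill-posed cases (single-class labels,
entirely missing columns, classes smaller than the fold or neighbour count)
raise errors naming the offending input.
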