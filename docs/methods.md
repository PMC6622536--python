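# Methods

## Data model

The unit of analysis is a cohort of subjects, each represented by one R×R
symmetric matrix of Fisher-Z-transformed Pearson correlations between
regional BOLD time series, plus a group label (healthy, MCS, UWS, or any
string). Diagonal entries are stored as 0 and ignored everywhere: the
self-correlation is identically 1 and its Z value is infinite, so it can
carry no information. Matrices are read from delimited text (comma or tab,
optional header row of ROI labels) via a manifest CSV; asymmetries up to
1e-8 are accepted silently, larger ones are symmetrized as (M + Mᵀ)/2 with
a warning rather than rejected, because externally produced matrices
routinely carry rounding asymmetry.

Group comparisons are pairwise. The virtual label `patients` expands to
MCS ∪ UWS at pairing time and is never stored. The positive class for
precision/recall defaults to the patient-side class (or the second class
when neither side is a patient group) and is configurable — nothing in the
method depends on the choice beyond the direction of the PR curve.

## Feature construction

A binary ROI mask keeps rows and columns of the matrix whose bit is 1.
The strict upper triangle of the truncated k×k matrix, read in row-major
order, is the SVM feature vector (length k(k−1)/2). Row-major order is an
arbitrary but fixed convention: any fixed order yields the same SVM, but
determinism requires choosing one. Masks with fewer than two active ROIs
have no pairwise feature and receive fitness 0 without error, so selection
eliminates them.

Internally the evaluator builds the full all-pairs design for a split once
and maps a mask to a column subset: both layouts share row-major
upper-triangle order, and per-column standardization commutes with column
selection, so the fast path is exactly equivalent to masking first (a test
asserts equality to machine precision).

## Classifier and fitness

Fitness is the average-precision form of the PR-AUC of SVM decision scores
on the held-out partition: AP = Σₖ (Rₖ − Rₖ₋₁) Pₖ over thresholds at each
distinct score, descending; tied scores form one threshold; the curve
starts at (recall 0, precision 1), the standard zero-predicted-positives
convention. Step integration rather than trapezoidal interpolation, since
linear PR interpolation is known to be optimistic. PR-AUC is preferred
over accuracy because the clinical cohorts the method targets are
imbalanced (e.g. 30/29/20 per group); under a class-label-independent
ranking its expectation approaches the positive-class prevalence, which is
also the natural chance floor.

The classifier is an L2-regularized hinge-loss linear SVM, C = 1, with
features standardized by training-partition statistics only (no test
leakage). Rationale: with tens of subjects and up to thousands of
correlation features the problem is firmly p ≫ n, where a linear maximum-
margin classifier is the standard choice; kernel (rbf available), C and
standardization are exposed in configuration. Decision-function values,
not hard predictions, feed the PR curve — a PR curve needs a ranking.
For throughput the linear path calls scikit-learn's compiled liblinear
routine directly (the study evaluates on the order of 10⁶ SVMs of ~30
samples, and the public estimator's per-fit validation overhead dominates
at that size); a regression test pins its decision values to the public
`LinearSVC(loss="hinge")` pipeline, and the solver's internal shuffling
seed is fixed so results are deterministic.

Train/test splits hold out a fraction 0.33 (test size = ceil(0.33 n)),
stratified by class by default — with 20 subjects in the smallest group,
unstratified splits would frequently produce single-class partitions,
which are an error at fit time.

## Genetic algorithm

Genotype: one boolean vector over ROIs. Defaults: population 1000, 100
generations, 5 elites, initialization density 0.25, deactivation-only
mutation at 0.1 per active bit. Parent selection is tournament of size 3
(scale-free in fitness, which matters because AP values cluster near 1),
crossover is single-point with probability 0.9; both are choices the
procedure leaves open and both are configurable. Founders drawn with
fewer than two active bits are redrawn.

Mutation never reactivates a bit (active sets only shrink along a lineage;
crossover is the only mechanism that reintroduces a 1), which together
with the fitness-tie rule — fewer active ROIs first, then lower population
index — provides the sparsity pressure. The population-index tie-break
deserves a note: breaking ties by the bit pattern instead (e.g.
lexicographically) systematically favors low-index ROIs among equally fit
masks and distorts the selection histogram toward them; the population
index is equally deterministic and indifferent to ROI identity.

Elites are copied unchanged and fitness of a fixed mask on a fixed split
is deterministic (and memoized), so the best-fitness trace is exactly
non-decreasing — asserted, not approximated, in the tests. Within a
replicate the same held-out split steers selection across generations;
this mirrors the procedure the package implements and means the final
best fitness is an optimistically biased estimate, which is precisely why
the replicate/sweep stage re-evaluates selected subsets on fresh splits.

## Replicate aggregation, sweep, permutation test

Deactivation-only mutation makes single runs prone to distinct local
optima, so the GA is repeated (default 1000×, each with a fresh split) and
ROIs are ranked by how often they appear in a run's best mask. The k-best
sweep evaluates the top-n ROIs for n = 2..n_max on fresh splits (n = 1 is
excluded — no pairwise feature exists) and reports the argmax of the mean
PR-AUC, ties to the smaller n. Each sweep repetition draws one split and
evaluates every n on it: pairing across n removes split-to-split noise
from the comparison of subset sizes and is n_max times cheaper than
independent draws. The with/without-selection comparison reuses the same
paired design (same splits for both arms).

The permutation test draws n ROIs uniformly at random (deliberately
ignoring the histogram — a pure, size-matched null), a fresh split per
draw, and reports the add-one p-value (#{null ≥ observed} + 1)/(draws + 1),
which can never return 0 and has floor 1/(draws + 1). The observed value
is a fresh mean evaluation of the selected subset, not the sweep maximum
(less optimistic). One master seed spawns per-replicate child seeds via
`numpy.random.SeedSequence`, so results are independent of execution order
and parallelization (`n_jobs`) cannot change them.

Default replicate counts (1000 runs, 1000 sweep repetitions, 100000
permutation draws) are the reference procedure's; the validation suite
and the reproduction script run scaled-down counts (50 runs, 100
repetitions, 1000 draws) with all statistical checks calibrated at those
sizes.

## Synthetic cohorts

Each class has a correlation template: unit diagonal, within-planted-set
off-diagonal entries ρ₀ (class 0) or ρ₁ (class 1), everything else ρ_b.
Subjects are T i.i.d. Gaussian vectors from the class template, reduced to
the sample Pearson correlation and Fisher-Z transformed — the same
pipeline applied to real data downstream of preprocessing. Templates are
checked positive semi-definite (an eigenvalue floor with entrywise repair
bound 0.05 covers rounding-level violations). Defaults: R = 30, planted
set of 5, ρ₀ = 0.1, ρ₁ = 0.7, ρ_b = 0, T = 400, 20 subjects per class —
class sizes mirror the scale of realistic clinical cohorts, and T is in
the range of a typical resting-state acquisition.

The equicorrelation-difference signal lives on *nodes* (every pair within
the planted set), matching the method's premise that regions, not single
edges, carry group information. What the generator deliberately omits:
temporal autocorrelation of BOLD (which shrinks the effective sample size
of a correlation estimate), between-subject heterogeneity of the true
covariance, site/scanner effects, and motion or physiological artifacts.
Passing tests therefore demonstrate the machinery — recovery of planted
nodes, calibration of the null, the selection-vs-no-selection direction —
not clinical effect sizes.

### Signal saturation

One consequence of the clean signal model is worth stating explicitly.
The sampling sd of a Fisher-Z entry is ≈ 1/√(T−3) ≈ 0.05 at T = 400,
while the planted effect is arctanh(0.7) − arctanh(0.1) ≈ 0.77 — about 15
sd per single edge. Any mask containing even one planted pair therefore
achieves held-out PR-AUC of exactly 1.0 on essentially every split. Three
visible effects on the reference cohort: the GA's best masks shrink to
2–3 planted ROIs (sparsity pressure has no fitness cost to resist); the
k-best sweep curve is flat at 1.0 from n = 2 onward, so its argmax (ties
to smaller n) is 2 rather than the planted size; and random-subset null
draws that happen to contain a planted pair (probability ≈ 0.18 for 5 of
30) tie the observed performance, bounding the permutation p-value near
that fraction. Node *recovery* is unaffected — the histogram still
identifies the planted set exactly — but sweep-peak location and
permutation significance only become informative when the per-edge effect
is on the order of its sampling noise, as it is in real cohorts. The
60-ROI cohort in the reproduction script (55 pure-noise ROIs) restores a
measurable selection-vs-no-selection gain because the all-ROI classifier
is diluted by noise features.

## Numerical and degenerate-input conventions

* `fisher_z` rejects |r| ≥ 1 by name; sample correlations of non-degenerate
  series never reach ±1 for T ≥ 3 (T < 3 is rejected).
* precision with zero predicted positives = 1; recall with zero actual
  positives is an error, as is PR-AUC without positives.
* Splits that would leave a class with fewer than 2 subjects are rejected
  before any GA work starts.
* liblinear tolerance 1e-4, max 20000 iterations, fixed internal seed;
  constant features get sd 1 during standardization instead of dividing
  by zero.
* Report floats are rounded to 12 decimals before JSON serialization;
  two runs from one master seed produce byte-identical reports.

## Known limitations

* The wrapper re-uses each replicate's test split across generations
  (by design, see above); reported per-run best fitness is optimistic.
  An internal-validation variant (fitness from a nested split of the
  training data) would be a natural extension.
* Deactivation-only mutation cannot recover an ROI lost from the entire
  population except through crossover with an elite that retains it;
  replicate aggregation, not any single run, is the unit of inference.
* The synthetic generator's homogeneous within-class covariance makes
  absolute performance numbers incomparable to real-data studies (see
  signal saturation above).
* No multiple-testing correction across group comparisons is applied.
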