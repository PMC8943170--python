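# Methods

## Model

Subjects are discrete symbol sequences of uneven length. Dissimilarity is
the Levenshtein edit distance computed by dynamic programming with costs
(insert, delete, substitute) = (1, 1, 2); a match costs 0. With these
defaults a substitution is exactly as expensive as a delete+insert, which
gives the closed identity `d(x, y) = |x| + |y| − 2·LCS(x, y)` — used
throughout the tests as an independent oracle. Costs are configurable; the
substitution branch of the recurrence tracks the configured substitute
cost. The DP uses a two-row rolling table; the within-row insertion
dependency is resolved by a running-minimum transform, so each row is a
handful of vectorized array operations rather than a Python inner loop.

Three normalizations address the dominance of sequence length in the raw
cost: division by the longer length (`k_ed2`, bounded by the substitute
cost), by the number of shared symbols (`k_ed3`), and by `2^|shared|`
(`k_ed4`, which strongly contracts distances between content-similar
pairs). "Shared symbols" counts the *distinct*-symbol set intersection,
not multiset multiplicity — the set reading of the `|x ∩ x'|` notation;
this was a genuinely open choice and the set reading was fixed once.
Two guards cover cases the formulas leave open: disjoint pairs divide by
`max(1, |∩|)` in `k_ed3`, and `k_ed4`'s denominator is evaluated as a
floating-point exponent (`d · 2^{−|∩|}`) so intersections beyond ~60
symbols underflow smoothly to 0 instead of overflowing an integer power.

## Distance-substitution kernel and its geometry

The kernel substitutes the edit distance into the polarization identity of
the translated dot product, relative to an origin sequence `x₀`:
`K(i, j) = ½(d(i, x₀) + d(x₀, j) − d(i, j))`, so `K(i, i) = d(i, x₀)`.
Because the *unsquared* edit distance takes the place of squared norms,
the construction is equivalent to embedding the metric's square root in an
L2 space: on line-embeddable data (single-symbol alphabets, where
`d = |ℓᵢ − ℓⱼ|`) the kernel takes the exact closed form
`½(|a| + |b| − |a − b|)` with `a = ℓᵢ − ℓ₀`, `b = ℓⱼ − ℓ₀` — a signed-min
(intersection-type) kernel, PSD by construction. On general sequence data
the edit metric is not L2-embeddable and the Gram matrix is indefinite;
its negative eigenvalue mass is reported by `is_psd` as a scale-free
diagnostic.

Indefiniteness is repaired, when requested, by eigendecomposing the
symmetrized matrix and transforming the spectrum: clip (`λ ← max(λ, 0)`),
shift (`λ ← λ − min(λ_min, 0)`), flip (`λ ← |λ|`) or square (`λ ← λ²`),
followed by reconstruction and re-symmetrization. Without a spectral step
the indefinite kernel is passed to the solver as-is (libsvm handles this
in practice) with the minimum eigenvalue logged. The default
post-processing order is spectral repair first, then cosine
normalization, then centering, each optional; the applied chain is
recorded in the kernel's provenance and round-trips through the matrix
store. Cosine normalization guards zero diagonal entries (possible only
for a degenerate origin) by zeroing the affected row/column and logging.
Kernel–target alignment is the uncentered Frobenius form
`⟨K, yyᵀ⟩ / (‖K‖_F · ‖yyᵀ‖_F)`; centered variants exist in the literature
and give different numbers, so alignment scores are comparable only within
this package.

## Learning and evaluation

Classification uses a soft-margin SVM on the precomputed kernel
(scikit-learn's libsvm binding). Evaluation is leave-one-out
cross-validation — appropriate for cohorts of tens to a few hundred
subjects — with the regularization constant chosen from the 4-value grid
{0.1, 1, 10, 100} by LOOCV F1. Choosing C on the same LOOCV that reports
performance is optimistically biased; the bias is accepted and documented
because the alternative (nested CV) is unstable at these sample sizes.
All tie-breaks are deterministic: smaller C wins, earlier zero-vector
candidate wins. A LOOCV fold whose training set degenerates to one class
predicts that class. The accuracy spread reported next to LOOCV accuracy
is the ddof-1 standard deviation of the per-fold correctness indicator.
The reported `nSV` comes from a final all-data fit at the selected C.

The origin `x₀` is selected greedily: *in-turn* mode excludes each subject
and uses it as the origin (n evaluations over n−1 subjects), *pool* mode
scans a held-out candidate set with the dataset intact. Both return the
full per-candidate table.

### Multiple kernel learning

`learn_weights` minimizes the SVM dual objective over simplex-constrained
kernel weights by reduced-gradient descent: the largest weight anchors the
equality constraint, zero-weight components with ascending reduced
gradient are frozen, and the step size is found by a bounded scalar line
search (Brent) on `[0, γ_max]`, where `γ_max` is the step to the first
boundary. The gradient at the dual optimizer is `−½ aᵀK_m a` with
`a = α∘y`. Stopping: relative duality gap `< 1e−2` (gap = best
single-kernel quadratic term minus current combination's), maximum weight
change `< 1e−4`, or 200 iterations; initial weights are uniform. Weights
below 1e−8 are zeroed and the simplex renormalized, reflecting the ℓ1
sparsity of the formulation. The objective trace is non-increasing by
construction of the line search. Two evaluation protocols are exposed:
the default learns weights once on all data and then LOOCVs the combined
kernel (fast, mildly optimistic), while `strict_loocv` re-learns the
weights inside every fold (unbiased, n-times costlier). They typically
agree when one kernel dominates; the default's optimism is of the same
kind as the vocabulary-level leakage accepted elsewhere at these cohort
sizes.

### Baselines

Bag-of-Words counts (and binary presence/absence) over the
lexicographically sorted dataset alphabet, with the vocabulary built from
the full dataset before cross-validation (the standard "one column per
distinct code" tabular setup; a mild, label-free leakage, noted here).
Raw counts, no TF-IDF; optional ℓ2 row scaling behind a flag, off by
default. Feature-space kernels: linear, polynomial (defaults c=1, d=3),
RBF `exp(−‖x−y‖²/2σ)`, exponential RBF `exp(−‖x−y‖/2σ)` and Laplace
`exp(−‖x−y‖/σ)` — the last two differ only by reparameterization of σ and
are kept as separately printed forms deliberately. σ defaults to the
median heuristic (median positive pairwise Euclidean distance). Logistic
regression is ℓ2-regularized (lbfgs, tol 1e−8, max 1000 iterations) with
its strength chosen from {0.01, 0.1, 1, 10} by LOOCV F1. Baseline kernels
run through the identical LOOCV/metrics code path as the edit kernels.

## Data ingestion

Event tables (one row per coded clinical event) are grouped by subject and
date-sorted; equal-date ties keep file order via a stable sort, making the
reader deterministic and invariant to row shuffles that preserve
equal-date order. Dates default to `YYYYMMDD`; the `"index"` format reads
integer event indices. The elevated-blood-pressure outcome labeller marks
a subject positive iff some reading strictly before the first
diabetes-diagnosis code reaches both thresholds (defaults 130/80 mmHg,
inclusive); how numeric readings attach to a pressure-examination code
varies across source systems, so the labeller takes a pluggable per-event
accessor instead of hard-coding a storage convention. Peptide tables are
character-tokenized with one-vs-all ±1 labels; class names are matched
case- and punctuation-insensitively, and an optional seeded balanced
subsample equalizes the class split. Matrices round-trip through
delimited text with a JSON provenance header at 17 significant digits
(value-exact for doubles).

## Synthetic data

The generator emulates the target regime — uneven lengths, discrete
alphabet, order-carried class signal — without imitating any real coding
ontology or visit-timing process. Each sequence is uniform random
background of length U(20, 120) over a 12-token alphabet into which a
6-token motif is spliced 6 times at random positions: class +1 receives
the motif, class −1 its reversal. The two motifs are constrained to share
one symbol multiset, so token histograms of the two classes are
identically distributed and any count-based featurization is at chance
*by construction*; the generator rejects motif pairs violating this.
Per-symbol replacement noise (default rate 0.05) controls difficulty.
Defaults were fixed once from a 20-seed design pilot confirming the
intended regime (edit-kernel LOOCV F1 at 1.0 on every seed, BoW-linear F1
0.21–0.64) and are not tuned per experiment. Passing tests on this
generator demonstrates that the pipeline recovers order signal under
length dispersion and noise; it does not demonstrate performance on real
clinical data, whose signal is weaker, whose alphabet is vastly larger,
and whose classes also differ in content and length distributions.

Problem sizes used by the test suite and the acceptance script (n = 60
subjects, candidate pools of 5, MKL problems of n ≤ 40, 500-pair distance
oracle sweeps) are chosen as the smallest sizes at which every claimed
property is exercised with comfortable statistical margin.

## Known limitations

- LOOCV model selection and full-dataset vocabulary/weight learning are
  optimistically biased; both are deliberate, documented trade-offs for
  small cohorts.
- The substitution kernel depends on the origin choice; the greedy search
  is a heuristic with no optimality guarantee.
- Spectral repair operates on the training Gram matrix as a whole;
  out-of-sample extension of a repaired kernel is not provided.
- Edit-distance computation is O(nm) per pair and O(N²) pairs; no banded
  or approximate variants are implemented.
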