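# Methods

## Model

`kronbind` treats compound–kinase binding affinity prediction as
pairwise kernel regression. Labels are pKd = −log₁₀(Kd in molar).
Given a compound kernel K_c (n_c × n_c) and a protein kernel K_p
(n_p × n_p), the pairwise kernel over (compound, protein) pairs is the
Kronecker product; KronRLS minimizes the regularized squared error of
the dual expansion f(c, p) = Σ a_{c'p'} K_c(c, c') K_p(p, p').

Two solvers implement this:

* **Complete labels** (`fit_complete`): with eigendecompositions
  K_c = U_c Λ_c U_cᵀ and K_p = U_p Λ_p U_pᵀ, the solution of
  (K_p ⊗ K_c + λI) vec(A) = vec(Y) is
  A = U_c [(U_cᵀ Y U_p) ⊘ (λ_c λ_pᵀ + λ)] U_pᵀ, costing
  O(n_c³ + n_p³ + n_c n_p (n_c + n_p)). Eigenvalues below 1e−12 of the
  largest are clipped to zero; with λ > 0 this behaves as a
  pseudo-inverse shift for near-singular normalized kernels.
* **Sparse labels** (`fit_cg`, the CGKronRLS setting): conjugate
  gradient on (S(K_p ⊗ K_c)Sᵀ + λI)a = y, where S selects the labeled
  cells. Each matrix–vector product scatters a into an n_c × n_p
  matrix, forms K_c A K_p, and gathers the labeled cells — the
  Kronecker product is never materialized. The objective is plain
  unweighted least squares on the labeled cells. CG starts from zero
  coefficients and is fully deterministic; it stops at `epochs`
  iterations or relative residual < `tol` (scipy `cg` with
  rtol = tol, atol = 0), whichever comes first. The iteration cap is
  deliberately exposed as a hyperparameter: truncated CG acts as
  early-stopping regularization, so `epochs` and λ are independent
  knobs tuned jointly by the grid ensemble. `epochs = 0` returns the
  all-zero model by definition.

Both solvers produce the same `KronRLSModel`; prediction evaluates
K_c A K_p with A the (scattered) dual matrix, which equals the
brute-force sum over training pairs.

**Model selection** uses nested leave-compound-out cross-validation:
the outer loop holds out all rows of one compound (mimicking blinded
evaluation, where test compounds have no public bioactivities); the
inner loop is grouped by compound and selects the hyperparameter
combination with the lowest held-out RMSE. Ties break by grid order,
so a grid listed in increasing λ prefers the smaller λ (the more
interpolating, better-conditioned model) reproducibly.

## Kernels

* **Compound kernels**: Tanimoto |a∧b|/|a∨b| or Dice 2|a∧b|/(|a|+|b|)
  over fixed-length bit fingerprints. Circular (Morgan) and path
  fingerprints are delegated to RDKit's generators; the contract the
  package enforces is determinism and bit length, not a particular
  hash. A pair of all-zero fingerprints is defined to have similarity
  0 off-diagonal (1 on the diagonal). Dice ≥ Tanimoto entrywise.
  The eight-kernel recipe used by the grid ensemble is
  {radius 2, 3} × {chirality on, off} × {Tanimoto, Dice} on 1024-bit
  circular fingerprints.
* **Protein kernels**: Smith–Waterman local alignment under affine
  gaps (a gap of length L costs open + L·extend), normalized as
  K(i,j) = sw(i,j)/√(sw(i,i)·sw(j,j)). The geometric normalization is
  chosen because it guarantees a unit diagonal and, for standard
  substitution matrices, entries in [0, 1]; the alignment engine is
  Biopython's `PairwiseAligner` (local mode), and tests verify it
  against a naive quadratic Gotoh dynamic program. Defaults are
  BLOSUM62 with gap open 11 / extend 1 — the ubiquitous protein
  defaults, configurable because no single convention is canonical for
  this application.
* **PSD repair**: normalized alignment matrices need not be positive
  semidefinite. `ensure_psd` adds |λ_min| + ε to the diagonal and
  renormalizes to unit diagonal. A diagonal shift (rather than
  eigenvalue clipping) preserves the ordering of off-diagonal
  similarities, which is what the regression consumes.

## Evaluation statistics

Six metrics score quantitative pKd predictions: RMSE; Pearson;
Spearman (average ranks on ties); concordance index (over all
pair-of-pairs with distinct measured values: concordant 1, tied
prediction 0.5, discordant 0 — equal to ROC-AUC when the measured
values are binary); F1 with both vectors binarized strictly at
pKd > 7; and the average of ROC-AUCs at ten evenly spaced binarization
thresholds spanning pKd ∈ [6, 8] inclusive (step 2/9), skipping
thresholds where only one class is present. Binarization is strict
(> cutoff) throughout; ties at a cutoff are negative.

**Bootstrap Bayes factor**: both prediction sets are scored on the
same resample (pairs drawn with replacement) in each of `n_boot`
iterations — the paired design removes the shared resampling variance.
K is the ratio of win counts in favor of the reference set with exact
ties split evenly; a zero denominator reports K = ∞ (serialized as
"inf"). Under this convention swapping the arguments yields the
reciprocal. **Ladder protocol**: the first submission is always
accepted; later submissions replace the reported score only when
K > 3 in their favor, preventing leaderboard climbing on resampling
noise.

**Permutation null**: the measured pKd vector is shuffled across the
pair set and the shuffled vector scored as a prediction of the
original; a model counts as better than random when it beats all
`n_perm` permuted scores. The empirical P is the fraction of null
scores at least as favorable as the observed one; calibration tests
verify super-uniformity of these P values when the observed score is
itself drawn from the null.

**Replicate upper bound**: between-study replicate pKd measurements
bound what any model can achieve. The replicate pool is first composed
to match the test set's fraction of inactive pairs (pKd = 5 in both
studies) by subsampling the inactive stratum, then bootstrap resamples
of the test-set size yield distributions of between-study Spearman and
RMSE.

**Balanced accuracy caveat**: challenge-style reports define balanced
accuracy as the mean of precision and recall. Because that collides
with the conventional sensitivity/specificity mean, the package
reports the precision/recall mean as `balanced_accuracy` and the
conventional quantity under the separate name
`balanced_accuracy_conventional`. Similarly, PPV and FDR are always
reported as a self-consistent pair (FDR = 1 − PPV whenever any
positive is predicted); published pairings violating this identity
cannot arise from one confusion matrix and are not reproduced.

## Ensembles

The grid ensemble fits one CGKronRLS regressor per
(λ, epochs, compound kernel) grid point — 5 × 11 × 8 = 440 with the
defaults λ ∈ {0.1, 0.5, 1.0, 1.5, 2.0}, epochs ∈ {400, 410, …, 500},
eight compound kernels, one shared protein kernel — and averages the
members uniformly. Members enumerate in lexicographic order so
failures are addressable by grid coordinates. Generic aggregation of
arbitrary prediction files supports mean, median and rank-weighted
rules; rank-weighted gives rank r of N files the weight N + 1 − r
(weights sum to N(N+1)/2, so the output is a convex combination), with
input order defining the ranking and earlier files winning ties.
Top-k curves mean-aggregate the first k of a pre-ranked list and
report Spearman/RMSE per k; the random-ensemble control scores
mean-aggregated uniform k-subsets and reports the fraction at least as
good as a reference (empirical P).

## Occupancy-based activity analysis

At equilibrium the occupied fraction of a protein at ligand
concentration L is L/(L + Kd), so
expected inhibition(%) = 100·L/(L + 10^−pKd). With L = 1 µM this gives
0.1% at pKd 3, 1% at pKd 4, 100/11 ≈ 9.1% at pKd 5, exactly 50% at
pKd 6 (dose = Kd) and 99.9% at pKd 9. The conversion is a strictly
increasing bijection from ℝ onto (0, 100) and depends on (pKd, L) only
through L·10^pKd. The combined activity predictor averages a measured
single-dose %inhibition (clipped to [0, 100]) with the expected
inhibition of a model-predicted pKd, fusing the two sources on a
common % scale; it is monotone in both arguments.

**Class enrichment**: compound–kinase pairs (not unique kinases — one
kinase recurs with several compounds) are ranked by absolute
prediction error, descending, ties broken by pair key for
reproducibility. For each kinase group/family, a weighted
Kolmogorov–Smirnov running sum increments member positions
proportionally to their absolute error (weight exponent 1, the
canonical choice) and decrements non-member positions uniformly; the
enrichment score is the extremal deviation, signed. The null permutes
class membership over pairs (rather than re-ranking), P values carry
an add-one correction (minimum 1/(n_perm + 1)), and
Benjamini–Hochberg controls the FDR across classes. Classes smaller
than 2 pairs or covering every pair are not testable and are skipped.

## Synthetic data generator

The generator emulates the statistical shape of a blinded two-round
kinase-profiling benchmark:

| parameter | default | meaning |
| --- | --- | --- |
| n_compounds × n_proteins | 40 × 30 | benchmark dimensions |
| n_compound_clusters | 5 | chemotype clusters (prototype fingerprints) |
| n_protein_families | 5 | kinase families (ancestor sequences) |
| fp_bits | 256 | fingerprint length (power of two) |
| seq_length | 300 | protein length — long enough for informative Smith–Waterman scores, short enough for desk-scale tests |
| bilinear_rank | 4 | rank of the ground-truth interaction matrix |
| noise_sd | 0.2 | assay noise, pKd units |
| frac_observed | 0.3 | fraction of cells observed |
| censor_floor | 5.0 | left-censoring at the 10 µM assay ceiling |

Compounds are cluster prototypes (bit density 0.12) with per-compound
bit flips (rate 0.05); proteins are family ancestors with point
substitutions (rate 0.10). These three rates were fixed once as
realistic: they give within-cluster Tanimoto ≈ 0.4–0.6 vs
between-cluster ≈ 0.1, and within-family sequence identity ≈ 80–90%,
comparable to chemotype series and kinase families. Ground truth is
the bilinear form K_c(UVᵀ)K_p of the generating kernels (U, V
Gaussian, rank `bilinear_rank`) min–max rescaled into pKd ∈ [4, 10],
the dynamic range of dose–response kinase assays. Observations add
Gaussian noise *before* censoring at the floor — assay noise happens
first, the 10 µM detection ceiling truncates afterwards. Single-dose
inhibition applies the occupancy formula to the true pKd, adds
Gaussian %-scale noise and clips to [0, 100]; the %-noise defaults to
25 × noise_sd (the %-scale image of the pKd noise near the occupancy
midpoint), so a noiseless pKd assay implies a noiseless single-dose
readout, and is overridable via `inhibition_noise_pct`.

**What passing tests on synthetic data do and do not show.** The
generator produces exactly the structure the model family assumes
(kernel-smooth, low-rank truth), so parameter-recovery results are an
upper bound on real-data behaviour: they validate the solvers,
plumbing and statistics, not chemistry. Real bioactivity data add
assay heterogeneity (Kd vs Ki vs IC50 shifts), non-random missingness
(two-step screening observes mostly high-inhibition pairs),
activity-cliff chemistry that fingerprints miss, and distribution
shift between training corpora and blinded test panels — none of which
the generator models. Synthetic compounds are fingerprint-level
objects only; chemically valid SMILES enter only through real data.

## Numerical choices and degenerate inputs

* Kernel matrices enforce symmetry within 1e−10 at construction and
  are symmetrized to machine precision internally.
* pKd conversion applies unit exponents as integer offsets, so
  powers-of-ten inputs convert exactly (10 nM → exactly 8.0).
* Correlations raise on zero-variance vectors; the concordance index
  raises when all measured values are equal; averaged AUC raises when
  every threshold is single-class; ROC/PR curves require both classes.
* Undefined PPV (nothing predicted positive) is flagged as NaN, not
  raised — screens with empty positive sets are a legitimate outcome.
* Replicate-pool composition errors (not enough inactive replicates to
  reach the target fraction) raise rather than silently re-weighting.
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds reproduce datasets, bootstraps, permutations and
  subsamples bit-for-bit.

## Scale of the shipped analyses

The test suite and examples run everything at desk scale, chosen as
the smallest sizes at which each property is meaningfully exercised:
solver-vs-oracle checks at up to 8 × 8 entities (dense Kronecker
oracles are cubic in n_c·n_p), parameter recovery at the generator's
40 × 30 defaults, bootstrap/permutation machinery at 200–2000
iterations in tests (the library defaults remain 10,000, the
convention for reported analyses), and null calibration at 100 seeds ×
200 permutations.

## Known limitations

* The CG solver implements plain unweighted least squares on observed
  cells; degree-weighted variants used by some pairwise-learning
  implementations are out of scope.
* The grid ensemble refits every member from scratch; no warm-starting
  across the epoch grid, which would be the natural optimization for
  large corpora.
* Enrichment P values come from label permutation only; competitive
  vs self-contained testing distinctions (as debated for gene-set
  analysis) are not modeled.
* Prediction-file validation enforces the package's own CSV schema
  (`compound_id, protein_id, pkd_pred`); foreign submission formats
  must be adapted upstream.
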