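# Methods

## Scope and model

`adaptsel` studies compound selection for QSAR training sets: given an
n × d table of molecular descriptors and an expensive-to-measure endpoint,
choose k ≪ n compounds whose measured values support the best PLS
regression for the rest. Two stepwise strategies (DescRep, PLS-Optimal) are
compared against five one-shot designs (Kennard-Stone, D-Optimal,
space-filling, MDC, random) under a repeated-split protocol that measures
not only mean error but dispersion, selection variability and robustness to
a structural outlier.

## Normalization and search spaces

Descriptors are min-max normalized to [0, 1]. Group-count descriptors are
zero for most compounds, so a normality assumption (standardization) is
untenable; min-max keeps sparse columns sparse. Constant columns map to
all-zeros rather than being dropped, keeping column indexing stable across
design/validation partitions. In the benchmark, normalization parameters
are fitted on the design partition only and applied to validation
compounds with clipping to [0, 1] — a conventional leakage-free choice.

One-shot selectors operate on the scores of the top five principal
components of the normalized table (three for the space-filling design,
whose cell count grows as b^a). The PCA is *uncentered* by default — the
cross-product decomposition of the raw [0, 1] matrix — matching the
protocol used for the structural-outlier definition; a `centered` flag
exposes covariance PCA since the choice for the search space is genuinely
open. All search spaces carry a pairwise Euclidean distance matrix rescaled
by its maximum, so distances are comparable across cycles and datasets.

Ties everywhere break to the lowest compound index, which makes every
deterministic selector bit-reproducible; the stochastic ones take an
explicit seeded generator.

## DescRep

Cycle 0 seeds `schedule[0]` compounds: k-means (15 restarts, random data
points as initial centers) partitions the 5-PC space; the restart with the
lowest total within-cluster pairwise distance wins and each cluster
contributes its medoid. Each later cycle:

1. **Descriptor scoring.** S_i = |Pearson r| between descriptor i and the
   endpoint over the *measured* compounds only (zero for constant columns);
   M = absolute descriptor-descriptor Pearson correlation over the full
   design set. Computing M on all design compounds rather than the measured
   subset is a deliberate stabilization: M is property-independent, and at
   n = 5–10 a measured-only M would be mostly noise.
2. **Descriptor selection.** Iteratively take argmax S, then down-weight
   S_i ← S_i (1 − M_ix)³. The cube annihilates duplicates (M = 1) and
   barely touches orthogonal descriptors (M = 0). If all scores hit zero
   the remaining slots fill by lowest index with a warning. Five
   descriptors per cycle by default, for parity with the 5-PC search space
   of the one-shot methods.
3. **Coverage exponent.** In the distance matrix of the selected-descriptor
   subspace, let d_k be the distance from the central compound (minimum
   distance sum) to its n_cover-th nearest neighbour, where n_cover =
   already-selected + batch size. exp = ln λ / ln(1 − d_k) with λ = 0.75,
   d_k clamped to [1e−9, 1 − 1e−9]. Dense neighbourhoods ⇒ large exp
   (sharp kernel); sparse ⇒ flat kernel. λ is exposed but reported to be
   insensitive over 0.5–0.9.
4. **Batch selection.** PS_x = ∏_{i∈selected} (1 − (1 − DM_xi)^exp). The
   batch minimizing the total PS over all compounds is found by exhaustive
   enumeration when the number of candidate combinations is ≤ 20 000, and
   greedily (one compound at a time, each minimizing the resulting total)
   beyond that; full enumeration is combinatorially infeasible for the
   larger batches. Because the seed is never empty, the "first compound"
   case reduces to the same PS product against the seed.

Selections are nested along the schedule by construction. A warm-start
(`seed_indices`) skips the k-means seed for campaigns with pre-measured
compounds.

## PLS-Optimal

The seed is a D-Optimal selection on the 5-PC space (the method's own
criterion applied to the only endpoint-free space available). Each cycle
refits a PLS model on the measured compounds (latent dimension 5, reduced
on rank deficiency), projects the whole design set onto the latent
variables, and extends the selection by Fedorov exchange with the current
selection held fixed.

## One-shot selectors

* **Kennard-Stone** starts at the central compound and repeatedly adds the
  compound with the maximal distance to its nearest selected neighbour.
* **D-Optimal** maximizes det(XᵀX) of the selected rows (intercept column
  appended; configurable) by Fedorov exchange: from a random feasible set,
  repeatedly apply the best determinant-increasing single swap, using the
  classical variance-function delta d(j) − d(i) − [d(i)d(j) − d(i,j)²] so a
  pass costs one matrix inversion rather than thousands of determinants.
  Ten restarts by default; the determinant trajectory is recorded and is
  non-decreasing by construction.
* **Space-filling** scans b = 1, 2, … bins per axis on three components
  until the nonempty cells reach the requested size; each kept cell (most
  populated first, ties by lowest linear index) contributes the compound
  closest to its center.
* **MDC** scores each compound by Σ_j w_j / r_ij, where r_ij ranks i in
  compound j's nearest-neighbour ordering; after selecting c, w_j ←
  w_j (1 − 1/r_cj) and w_c ← 0. The literature leaves the exact functional
  form open; this reciprocal-rank instantiation is isolated behind one
  function so alternates can be swapped. A fixed count is selected instead
  of a stop criterion.

## PLS evaluation model

Each selection is scored by a PLS regression on *all* normalized
descriptors of the selected compounds — not the low-dimensional search
space. The latent-variable count maximizes 5-fold cross-validated R²
(seeded shuffled folds; each fold scored against its own observations with
the training-fold mean as baseline — the Q² convention; ties to the
smaller count). The candidate cap min(10, n_train − 2, d), further limited
to n_train − ⌈n_train/5⌉ − 1, protects the n = 5 regime; below 5 training
compounds CV degrades to leave-one-out with a warning. Validation metrics
are RMSE and Pearson r; constant predictions record r = 0 with a flag.

## Robustness protocol

250 independent 84/16 splits by default (the scaled studies below use
fewer). Per split, one-shot methods restart from scratch at every sample
size; adaptive methods run once along the whole schedule. The summary per
(method, size) reports mean RMSE, mean r, RMSE standard deviation across
trials, and selection variability (distinct compounds selected across all
trials). Paired method comparisons use the exact two-sided sign test at
p = 0.5 with ties dropped. Failed trials are recorded and excluded, with
counts reported.

An optional structural disruptor (a raw descriptor row plus its endpoint
value) is appended to every design partition *before* normalization, so it
stretches the descriptor ranges exactly as re-normalizing an extended
dataset would; it never enters a validation partition, so it can only act
through selection and training.

## Synthetic data

The generator emulates the statistical shape of a small-molecule descriptor
table: two dense continuous descriptors (lipophilicity/solubility-like,
anticorrelated at ρ = −0.7 by default) plus 200 sparse non-negative
group-count descriptors that are zero with probability 0.9 (Bernoulli
presence × half-normal magnitude). The endpoint is linear in a small driver
set — by default both dense descriptors and the first two sparse ones,
weights (1.0, −0.8, 0.6, 0.5) — plus Gaussian noise (SD 0.3 in endpoint
units, ≈ 0.2 of the endpoint's SD), with an optional mild quadratic term.
Driver sparse columns are drawn at a reduced zero-fraction (≤ 0.5): the
chemically informative groups are the common ones. The generating truth
(drivers, weights, noise) is always returned for recovery checks.

What this emulates — and what it does not: the marginal sparsity and
dimensionality of real group-count tables, a low-dimensional linear
structure–property relationship, and a controlled outlier. It does not
emulate fragment co-occurrence structure, multi-modal chemical families,
activity cliffs, or heteroscedastic measurement error; conclusions from
passing tests are about algorithmic behaviour under the stated statistical
conditions, not about any specific chemistry.

The structural disruptor is built as a "large atypical molecule": the
column-wise median row, raised to the observed column maximum on every
common (top-half-variance) descriptor simultaneously — no single value out
of range, but the conjunction rotates the leading principal components
(loading cosine shift ≈ 0.9) — and pushed beyond range on a handful of
near-constant columns it alone occupies. The magnitude is scaled until the
detector certifies at least the requested trimmed-SD distance (default 5).
Its endpoint value is drawn from the same generative law: a validly
measured but structurally unrepresentative compound.

## Disruptor detection

A candidate row is a disruptor when, with the PCA recomputed on the table
plus candidate, its score on PC1 or PC2 lies ≥ 5 standard deviations from
the mean of the central 97% of the other compounds' scores (both moments
from the trimmed set). The loading rotation, 1 − |cos| between loadings
with and without the candidate, is reported per component but does not
enter the boolean — no principled threshold exists for it. Tables below 34
compounds are rejected (a 97% trim is meaningless there).

## Problem sizes and numerical choices

The shipped studies use n = 300 compounds (202 descriptors) with 50 trials
for the DescRep-vs-random comparison, 20 paired trials for the outlier
study, and 25 replicates of n = 150 for driver recovery — sizes at which
the Monte-Carlo summaries are stable enough to compare methods while the
full grid remains cheap to recompute. Driver recovery is assessed on a
10/20/30 schedule: Pearson ranking among ~50 descriptors is noise-dominated
below ~15 measured compounds (spurious correlations at n = 7 routinely
exceed a moderate driver's true correlation), so a recovery claim at the
5/7/10 schedule would measure sampling noise, not the refinement.

Degenerate inputs are handled explicitly: identical points give an all-zero
distance matrix with a warning; rank-deficient PCA returns the available
components with a warning; a singular information matrix at every Fedorov
restart raises; exhausted descriptor scores fill by lowest index with a
warning; all-tied sign tests return p = 1 with a flag.

## Known limitations

* Greedy batch selection beyond 20 000 combinations is an approximation to
  the exhaustive rule; it is exact for batch = 1 and matches enumeration on
  all tested small instances but carries no optimality guarantee.
* DescRep's Pearson-based refinement is leverage-sensitive: a single valid
  but extreme measured compound can tilt the descriptor ranking at small n.
  The outlier study quantifies this; robust correlation variants are an
  obvious extension and deliberately out of scope.
* The exponent rule assumes the distance matrix is max-normalized; spaces
  with many exact duplicates drive d_k → 0 and the clamp takes over.
* k-means seeding is not permutation-equivariant (restart draws depend on
  row order); the adaptive cycles themselves are.
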