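# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Data model and preprocessing

A block is a samples × features numeric matrix with unique string ids on
both axes; values must be finite (imputation is upstream — the library
refuses missing cells rather than guessing). Metadata maps every sample to
a class label, optionally with a hex color per class. `harmonize` restricts
all blocks to the samples present everywhere and orders them ascending
lexicographically; the fixed order makes cross-validation fold assignment a
pure function of the seed.

Upload-time filtering dispatches on block type:

* **Feature cap** (non-microbiome blocks over 10,000 features): first drop
  columns with sum < 10 (strict), then drop the columns with the smallest
  median absolute deviation until exactly 10,000 remain. MAD is used
  *without* the 1.4826 normal-consistency constant — only the ranking
  matters and a positive constant cannot change it. Ties at the MAD cutoff
  keep earlier columns (stable sort). The cap exists because sparse PLS
  tuning cost and memory grow with width, not because the solvers require
  it; below the cap the step is the identity.
* **Compositional transform** (microbiome count blocks): remove features
  whose total raw count is ≤ 10⁻⁴ × grand total, computed on raw totals
  *before* the +1 offset; then offset, total-sum-scale each sample, and
  apply the centered log-ratio. TSS before CLR is recorded for transparency
  but is mathematically irrelevant: CLR output is invariant to any
  per-sample rescaling (the tests assert this). The threshold comparison
  (≤ by default) and strictness are configurable because the 0.01 % rule's
  boundary semantics vary between descriptions of the recipe.

The 50 Mb upload bound of GUI deployments is logged as a warning only; it
is not an algorithmic limit.

## Latent-variable solvers

All solvers center and unit-scale columns (sample sd, ddof = 1) and are
fully deterministic — no RNG anywhere in the fitting path. Sparsity is one
primitive: soft-threshold a weight vector at its (keep+1)-th largest
magnitude, leaving at most `keep` nonzeros (exact magnitude ties at the
cutoff shrink to zero together; ranking ties keep the earlier index, and a
fully tied vector keeps its first-ranked entry so the direction never
collapses). Converged weight columns are sign-fixed so their
largest-magnitude entry is positive, making runs and implementations
comparable. Convergence is max-abs weight change < 1e-9 with at most 500
iterations; non-convergence raises a *tunable failure* consumed by the
repair loop rather than a hard error.

* **PCA** is an exact SVD; the full explained-variance spectrum over all
  min(n−1, p) components is stored so the 80 % rule can always be applied.
* **sPCA** runs per component: seed with the residual's leading right
  singular vector, alternate u ← Xv/‖Xv‖, v ∝ soft(Xᵀu, keep), then
  deflate the residual by t vᵀ (t = Xv).
* **sPLS** seeds the Y-weight from the leading right singular vector of the
  current XᵀY and alternates a ∝ soft(Xᵀu, keepX), b ∝ soft(Yᵀt, keepY).
  Regression mode deflates both blocks on the X-score t (hence swapping X
  and Y changes the result); canonical mode deflates Y on its own score u.
  Canonical mode is *still* asymmetric under block exchange because the
  initialization comes from XᵀY's right singular vector; this mirrors the
  behavior of the wrapped algorithm family and is left as is.
  With full keeps and one component the solution equals the SVD of the
  scaled cross-covariance; the tests verify this, and verify that both
  modes reproduce the reference R implementation's dense loadings to
  ~1e-12 and its sparse support exactly (frozen oracle under
  `tests/oracles/`).
* **sPLS-DA** is regression-mode sPLS against the one-hot class matrix
  (column order = sorted labels); the class side is never sparsified.
* **DIABLO** (multiblock sPLS-DA) appends the one-hot block with connection
  weight 1 to every data block and maximizes the design-weighted sum of
  score covariances by block coordinate ascent, soft-thresholding each data
  block's weight; every block is deflated on its own score. For K classes
  the class block has rank K−1, so its residual is exactly zero afterwards;
  such exhausted blocks sit out of later components with zero weight
  instead of failing (with a binary outcome, component 2 is therefore
  driven by the data–data design terms alone).
* **Prediction** projects new samples by replaying the deflation sequence.
  Distances: `max` (argmax of the least-squares dummy prediction),
  `centroids` (nearest training-class centroid in score space, the default
  everywhere), `mahalanobis` (pooled within-class score covariance,
  ridge-stabilized by 1e-12·I). DIABLO combines per-block predictions by
  majority vote; ties go to the block whose component-1 scores correlate
  best with the class indicators.

## Selection rules and tuning

* PCA components: smallest H with cumulative explained variance ≥ 0.80.
* (s)PLS components: per component h, PRESS is accumulated by refitting one
  dense component on the training rows of the (full-data-deflated)
  matrices and predicting the held-out Y residuals from the X score;
  Q²_h = 1 − PRESS_h/RSS_{h−1}, pooled over all Y columns (a single
  ratio of sums, not a mean of per-column ratios). The retained count is
  the *last* component with Q² > 0.0975; if none passes, 1 (fallback).
* Discriminant models: component count and keeps minimize CV mean BER
  (centroids distance by default; `max` available). Ties always favor
  fewer components / smaller keeps — parsimony, and deterministic.
* Pairwise keeps: per component, each (keepX, keepY) pair is scored by the
  mean over repeats of |cor| between the pooled CV-predicted held-out
  scores and the full-data fit's scores, averaged over the t and u sides;
  pairs are scanned in ascending order so ties favor smaller keeps.
* DIABLO keeps: per component, blocks are scanned sequentially, each
  block's grid evaluated with the other blocks held at their current best
  (cost linear in the number of blocks rather than the full cartesian
  product; with few blocks and strong signal the sequential optimum
  coincides with the planted configuration in the benchmarks).
* sPCA keeps (the PCA path): tuned by the same CV score-correlation
  criterion as pairwise sPLS, sharing the keep grid.

Folds default to min(5, smallest class size) — a 12-sample, 4-class design
forces 3 — with 10 repeats and a mandatory seed. Stratified folds deal each
class round-robin after a seeded shuffle, so every fold keeps the class
proportions; pairwise (label-free) tuning uses plain seeded folds. The
default keep grid is {1..10, 15, 20, 25, 30, 40, 50} truncated at each
block's width. The whole tuning stack is a pure function of (data,
parameters, seed): results are bit-identical on rerun.

**Near-zero-variance repair.** A tunable failure (constant column under
scaling, non-convergence, degenerate score) triggers: compute the
uniqueness percentage (100 × distinct/n) of every column of the implicated
block(s) — both for a pairwise model, only the failing blocks for
DIABLO — remove *all* columns of the block holding the global minimum that
attain it, log the removal, restart. The loop aborts once a repaired block
would fall below 2 features (configurable); feature counts strictly
decrease, so termination is guaranteed.

**Design matrix.** Each block pair is fitted with dense canonical PLS (one
component) and |cor(t₁, u₁)| recorded; the minimum over pairs fills every
off-diagonal cell, floored to the nearest tenth below by default (flooring
is an option because published analyses report the floored value while the
raw minimum is what the data give). A manual value always overrides.

## Association networks

The similarity between feature i of block A and feature j of block B is
Σ_{h≤H} cor(xᵢ, t_h^A)·cor(yⱼ, t_h^B), each feature correlated with its
*own* block's scores (t and u for a PLS pair); with orthogonal within-block
scores the value is bounded by 1 in magnitude. Edges require |similarity|
strictly greater than the cutoff ("higher than"); nodes without edges are
dropped, so edge sets are monotone non-increasing in the cutoff. Circos
exports attach per-feature class-mean profiles of the standardized values.
GraphML and JSON node-link exports round-trip losslessly; heatmap-ordered
(dendrogram) output is available but optional.

## Synthetic data generator

Each sample draws a latent factor vector: its class mean plus standard
normal noise. Class means sit on a simplex with equal pairwise distances of
`class_separation` (default 3.0; the unit is factor-noise standard
deviations, so separation 3 means moderately but clearly separated
classes). Per block, only `n_informative` features load on the factors;
loading magnitudes are `loading_strength` × (0.5 + |N(0,1)|)/√m with random
signs, bounded away from zero so every planted feature is in principle
recoverable. Continuous blocks add Gaussian noise (`noise_sd`); count
blocks draw one multinomial of `library_size` reads per sample with
probabilities softmax(signal + baseline), where the per-feature baseline is
N(0, `abundance_sd`) on the log scale — a lognormal-type taxon abundance
profile that produces the many rare features of real ASV tables
(`abundance_sd = 0` gives near-uniform taxa). Structure (which features are
informative, their loadings, baselines) and sampling noise come from
separate child streams of the seed, so `planted_truth` reproduces the
informative set without generating data.

The case-study-shaped fixture mirrors a 12-sample, 4-class design with
blocks of 23 (continuous), 4,398 and 3,252 (ASV counts, `abundance_sd`
2.5, library 50,000) and 27,964 features (read counts, *not* microbiome,
library 2,000,000, `abundance_sd` 1.5) — chosen so the oversized block
exercises the feature cap and the count blocks lose a realistic majority of
their taxa to the 0.01 % rule.

What the generator does *not* emulate: zero-inflation beyond multinomial
sparsity, taxon–taxon ecological interactions, batch effects, library-size
variation, or heavy-tailed continuous noise. Passing benchmarks therefore
show that the pipeline recovers planted low-rank class structure under
idealized noise, not that it is robust to the full messiness of real data.

## Benchmark conditions and problem sizes

The recovery benchmarks use a strong planted effect: `loading_strength` 3,
`class_separation` 4, two classes of six samples, 3-fold CV with 2–3
repeats; the single-block benchmark plants 5 informative features among 50,
the three-block benchmark 4 among 20 per block (binary phenotype — with a
two-class outcome one component suffices, which matches how the multiblock
model is strongest; on few-sample multi-class designs its later components
are weak, a behavior the reference R implementation reproduces almost
exactly and that is inherent to the method, not to this implementation).
Grids in the tests and the acceptance script are small supersets of the
planted sizes ({3,5,8}-style) to keep the default runs fast; the full
default grid is available and unchanged. Under these conditions the tuned
models recover ≥ 80 % of planted features with mean CV BER well under 0.1
across 20 seeds, and a zero-strength block calibrates to chance BER
(K−1)/K within ±0.1 over dozens of seeds.

## Known limitations

* Sparse NIPALS converges to a local optimum; with very small n and many
  correlated noise features the selected support can miss a planted pair
  even when it is the single strongest correlation (the initialization from
  the cross-covariance SVD is then dominated by accumulated noise). More
  samples, or pre-reduction by the single-omics step, resolves this.
* Q² on unreduced blocks is diluted by noise response columns (it predicts
  the whole Y matrix); the workflow therefore applies it after single-omics
  reduction, as the three-step design intends.
* Only regression and canonical deflation are implemented; no invariant /
  classic modes, no unsupervised multiblock variant, no GPU paths.
* The interactive network viewer of GUI ancestors is out of scope; exports
  carry all attributes a viewer needs.
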