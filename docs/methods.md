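# Methods

## Problem and model

Given a binary disease × miRNA adjacency matrix `A ∈ {0,1}^{nd×nm}` of
verified associations and up to three precomputed similarity kernels
per side, the pipeline scores every pair for the plausibility of an
unobserved association.  The underlying assumption is the standard one
for this family of methods: functionally similar miRNAs tend to
associate with phenotypically similar diseases, so association labels
can be spread along similarity edges.  `A` is oriented disease × miRNA
(`nd × nm`) everywhere; row `i` is the interaction profile of disease
`dᵢ`, column `j` the profile of miRNA `mⱼ`.

The five stages, in execution order:

1. **GIP kernels** — `exp(−ρ‖K(xᵢ)−K(xⱼ)‖²)` per side with
   `ρ = ρ′ / mean‖K(x)‖²`.  The diagonal is set to exactly 1 and the
   kernel inherits symmetry from the distance matrix.
2. **Similarity kernel fusion** — column-normalized kernels `Pₙ`
   cross-diffused through per-kernel neighbor-constraint kernels `Cₙ`
   (row-normalized over each entity's k nearest neighbors including
   itself), iterated synchronously until the largest elementwise change
   drops below a tolerance, averaged, masked by the mutual-KNN weight
   `W ∈ {0, ½, 1}`, symmetrized.
3. **WKNKN densification** — each entity's profile is reconstructed
   from its K most similar *verified* neighbors (entities with ≥ 1
   known association, the entity itself excluded) with weights
   `t^(i−1)·S(i,r)` and normalizer `Σᵢ S(i,r)`; the two side
   reconstructions are blended with weights `(δ₁, δ₂)` and applied as
   `A ← max(A, A_md)`.
4. **Improved label propagation** — row-stochastic KNN local affinities
   (self excluded) drive `Xᵗ = γ·aff·Y + (1−γ)·Xᵗ⁻¹` with constant
   source `Y` (the densified `A`, transposed on the miRNA side) from
   `X⁰ = Y`; the side score is the running sum `ΣX^i` including the
   final iterate.
5. **Ensemble** — `F = α·F_d + (1−α)·F_mᵀ`.

## Parameters

| stage | parameter | default | meaning / rationale |
|---|---|---|---|
| GIP | `base_bandwidth_{disease,mirna}` (ρ′) | 1.0 | established GIP convention; effective ρ adapts to data density |
| fusion | `beta` (β) | 0.5 | balance of cross-diffusion vs. initial kernels; value exposed, no canonical choice |
| fusion | `k_neighbors` | 20 | neighbor-constraint and mutual-mask size; clipped to n at use |
| fusion | `max_iterations` / `tolerance` | 20 / 1e-6 | diffusion iterates contract quickly in practice; cap guards pathological inputs |
| WKNKN | `k` (K) | 10 | verified neighbors per entity |
| WKNKN | `decay` (t) | 0.7 | geometric down-weighting of lower-ranked neighbors |
| WKNKN | `delta_disease`, `delta_mirna` (δ₁, δ₂) | 0.5, 0.5 | equal blending of the two side reconstructions |
| propagation | `gamma` (γ) | 0.2 | absorb vs. retain balance — the tuned value |
| propagation | `alpha` (α) | 0.3 | ensemble weight on the disease-side scores — the tuned value; the alternative convention α = 0.5 is available via config |
| propagation | `k_neighbors` | 20 | local-affinity sparsity |
| propagation | `tolerance` / `max_iterations` | 1e-6 / 1000 | stop when max elementwise change < tolerance |

All parameters live in `PipelineConfig` and can be supplied as YAML to
the CLI.  Unknown keys are rejected rather than ignored.

## Design choices where the design was open

* **Propagation recursion.**  The default `as_printed` mode uses the
  constant source term `γ·aff·Y`: the update is an affine contraction
  with factor `1−γ`, has the closed form
  `Xᵗ = (1−γ)ᵗ·Y + (1−(1−γ)ᵗ)·aff·Y`, and converges for every γ > 0
  — the property the test suite checks to 1e-10.  A `recurrent` mode
  (`γ·aff·Xᵗ⁻¹ + (1−γ)·Y`, the conventional propagation in which labels
  diffuse through multi-step neighborhoods) is provided for comparison;
  its fixed point solves `(I − γ·aff)·X = (1−γ)·Y`.
* **Mutual-neighbor mask.**  `W` multiplies the fused kernel
  elementwise — it is a {0, ½, 1} noise gate, and a matrix product
  would destroy that semantics.  Its neighbor sets are computed on the
  symmetrized average of the diffusion iterates (the object in scope at
  that stage).
* **Score accumulation** includes both `X⁰` and the final converged
  iterate.
* **Self-membership.**  Neighbor-constraint kernels include self (the
  diagonal dominates a similarity kernel and anchors the row); local
  affinities exclude self, because self-retention is already the
  `(1−γ)` term and including it would double-count.  WKNKN excludes the
  query from its own neighbor list, since a verified entity would
  otherwise trivially reconstruct itself.
* **WKNKN normalizer** sums the raw similarities of the selected
  neighbors without the decay factor.  Consequence: with `decay = 0`
  only the top neighbor contributes weight while the normalizer still
  counts all K similarities, shrinking the reconstruction — the
  behavior is pinned by a test so the asymmetry is explicit rather than
  accidental.
* **Ties** in every neighbor selection and in candidate ranking break
  by ascending index/label, making all operations deterministic.
* **Order independence.**  `ilpmda_predict` sorts entities by label
  internally and restores the caller's order on output, so predictions
  are bitwise identical under any joint permutation of the inputs
  (floating-point reductions would otherwise differ at the last ulp).
* **Kernel count.**  Fusion accepts any number of kernels ≥ 1 — the
  cross term generalizes to `mean_{t≠n} P_t`; with a single kernel the
  column-normalized, symmetrized kernel is returned unchanged.  The
  full pipeline fuses the provided kernels plus the GIP kernel per side.

## Numerical conventions and degenerate inputs

* Similarity kernels must be symmetric within 1e-10, nonnegative and
  finite; stochastic kernels must have unit (or exactly zero) sums
  within 1e-10 along their orientation.
* An all-zero association matrix has no defined GIP bandwidth and
  raises a dedicated error; an all-zero kernel column cannot be
  column-normalized and names the offending entity.
* Rows with zero neighbor mass in the neighbor-constraint kernel or
  local affinity stay all-zero (isolated entities neither receive nor
  give labels) — with a warning in the former case.
* `k` larger than the candidate pool is clipped with a warning.
* WKNKN output is clipped to [0, 1] to absorb last-ulp float spill in
  the convex combinations.
* TSV values are written with 12 significant digits; write → read is
  the identity at that precision and a fixed point thereafter.

## Cross-validation protocol

Held-out positives are zeroed in a training copy **before** the GIP
kernels, fusion and WKNKN are recomputed; anything less recomputation
leaks the test label through the interaction profiles.  Candidate
negatives are all pairs unknown in the *full* matrix, scored by the
same runs.  Global LOOCV therefore costs one pipeline run per known
association; repeated k-fold CV costs `folds × repeats` runs, with fold
assignments drawn from a single seeded generator so results are
reproducible and independent of the `max_workers` process count.
A leak audit inside the harness asserts that no training matrix
contains its test positives.

## The synthetic benchmark

`generate_benchmark` plants a rank-`r` structure: nonnegative
Gamma(2, 1) latent factors `U (nd×r)`, `V (nm×r)` define planted scores
`P = U·Vᵀ`; the positive set is the top `density` fraction of `P`,
seeded so that every disease's and every miRNA's single top-scoring
pair is always included (association catalogues only list entities
with at least one verified association, and pure global thresholding
of a low-rank matrix would leave low-norm entities empty).  Each
similarity kernel is the cosine similarity of the side's latent rows
plus symmetric N(0, σ²) noise, clipped to [0, 1] with forced unit
diagonal.  Defaults: nd = 60, nm = 80, rank = 4, density = 0.08,
σ = 0.1, 3 kernels per side, seed 42.

What it emulates: a sparse bipartite matrix whose positives follow a
low-dimensional geometry, observed through several noisy but
informative kernels — the regime the method assumes.  What it does
not: the heavy-tailed degree distribution of real catalogues, biased
(study-driven) missingness, block/ontology structure in disease
similarity, or kernels whose noise is correlated with the association
labels.  Passing the recovery tests therefore shows the pipeline
recovers planted low-rank structure under its own assumptions, not
that it attains any particular AUC on real databases.

## Problem sizes used in the shipped analyses

The acceptance script evaluates 5-fold CV (3 repeats) at the default
60 × 80 conditions, runs global LOOCV on a 30 × 40 benchmark (96
positives, hence 96 full pipeline reruns), and one masked-recovery run
at 60 × 80 — sizes chosen to exercise every protocol end to end at
desk scale.

## Limitations

* Semantic/functional/sequence similarities are consumed as files;
  computing them from MeSH, miRBase or gene sets is out of scope.
* The candidate-negative convention treats all unknown pairs as
  negatives; true-but-unverified associations deflate the measured AUC.
* LOOCV is O(#positives) pipeline runs and is intended for desk-scale
  matrices; use k-fold CV for catalogue-scale data.
* Real-data headline numbers depend on the specific association
  catalogue and kernel provenance and are not reproduced by the
  synthetic benchmark.
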