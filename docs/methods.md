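# Methods

## Model and estimators

Spot expression is modeled as a linear mixture of reference prototypes,
`Y = M X + E`, with `Y` the spots × genes count matrix, `X` the cells ×
genes reference (each row one prototype carrying a cell-type label), `M` the
unknown spots × cells weight matrix, and `E` unstructured noise. The model
uses no spatial smoothing: each spot is deconvolved independently, and
coordinates are only used for plotting.

**OLS / SLS.** The unconstrained minimizer of `½‖Y − MX‖²_F` is
`M̂ = Y Xᵀ(X Xᵀ)⁻¹`. When `X` is rank-deficient (common when a noiseless
reference contains identical prototypes, or with very few genes) the
minimum-norm solution via the pseudo-inverse is used instead and flagged on
the result. SLS aggregates by summing OLS weights within each cell type and
clamping each per-type **sum** at zero before normalizing — the clamp acts on
type sums, not individual entries, so a type with mixed-sign prototype
weights keeps its net contribution.

**NNLS.** The ridge-penalized non-negative problem
`argmin_{M≥0} ½‖Y − MX‖²_F + (λ/2)‖M‖²_F` is solved by projected gradient
descent: `M ← max(M − lr·((MX − Y)Xᵀ + λM), 0)`. Properties of this
implementation:

* fixed step size (`learning_rate`), no line search, exactly `num_epochs`
  iterations, no early stopping — runs are bit-reproducible and convergence
  is asserted by KKT checks on the returned iterate rather than monitored in
  the loop;
* warm start at `max(M̂_OLS, 0)` (on by default) — the clamp keeps the first
  iterate feasible; with noiseless data and a feasible OLS optimum the warm
  start is already the solution;
* divergence (non-finite iterates, possible when `lr ≥ 2/(σ_max(X)² + λ)`)
  raises an error advising a smaller learning rate. With the per-cell
  normalized reference, `σ_max(X)²` is small and the defaults are stable.

**Aggregation.** Proportions of type k at spot i are the type's summed
weights over the spot's total (non-negative weights for NNLS; clamped type
sums for SLS). Spots whose denominator vanishes (all-zero weights, or all
type sums non-positive) receive a uniform row `1/K` and a warning naming the
spot indices; this keeps every row on the simplex, which downstream metrics
and plots assume. Type columns are ordered lexicographically by name.

## Ridge selection

Cross-validation splits **genes** (columns), not spots: a seeded permutation
of the gene indices is cut into `n_fold` contiguous blocks; for each
candidate λ and fold, the model is fit on the training columns and scored on
the held-out columns by `MMSE(λ) = ‖Y_test − M̂ X_test‖²_F / (2 n_test)`.
The constants do not affect the argmin but are kept so reported values match
the definition exactly. The λ minimizing the fold mean wins, ties going to
the smaller λ (less bias when indifferent); the model is then refit on the
full gene set with the winner. The default candidate grid is
`0, 0.02, …, 0.2`; the default fixed penalty (when no grid is given) is
`λ = 0.1`.

## Preprocessing

Three ordered steps, applied to a gene-aligned reference/spatial pair:

1. **Per-cell normalization** (`cellcount_norm`, default on): each reference
   cell divided by its total count. Zero-total cells are dropped with a
   warning first. Spatial counts are left raw — the mixing model regresses
   raw spot counts on normalized prototype profiles, and the per-spot
   normalization in the aggregation step absorbs the depth scale.
2. **Rare-type removal** (`cellcount_min`, default 2): types with fewer
   cells are removed with their cells; relative cell order is preserved.
3. **Marker selection** (`gene_top`, default 200): genes are ranked per type
   by a one-vs-rest tie-corrected Wilcoxon rank-sum z statistic on log1p
   expression (upregulated-in-type first; rank statistics are invariant to
   the monotone transform, which matters only for the alternative Welch
   t-test ranking, selectable via `de_method`). Ranking ties break by gene
   id. The union of per-type top lists, sorted by gene id, becomes the
   working gene set for both datasets.

Gene alignment matches identifiers exactly (case-sensitive), rejects
duplicates rather than summing them, and sorts the intersection
lexicographically so results do not depend on input column order.

## Synthetic data

The generator instantiates the mixing model directly, which is what makes
exact-recovery testing possible: K type signatures are drawn from a sparse
Dirichlet over genes (concentration `signature_strength`, default 0.1 —
small values give distinct, nearly disjoint expression programs); reference
cells are Poisson draws around `depth × signature`; true spot compositions
come from a Dirichlet on the simplex (concentration `proportion_prior`,
default 1 = uniform); spot counts are Poisson draws around
`depth × (P_true @ signatures)`. `noise_model="none"` replaces every draw
with its expectation, making the linear model exact. Defaults — 3 types,
50 cells/type, 300 genes, 100 spots, depth 10⁴ — are large enough to
exercise cross-validation folds and small enough for seconds-scale runs;
these sizes are also what the test-suite fixtures and the acceptance script
use.

Ground truth lives at the type level; the implied prototype weights split a
type's mass equally among its prototypes (any split with the same type sums
is observationally equivalent under the aggregation). What the generator
does **not** emulate: platform artifacts such as spot-size variation,
segmentation error, zero-inflation beyond Poisson, batch effects between
reference and tissue, or spatial correlation of compositions. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to real-data violations of them.

## Metrics

* **RMSE** pooled over all spot × type entries (the per-spot-then-average
  variant differs only in weighting; pooled is the common convention).
* **JSD** per spot with log base 2 (`½KL(p‖m) + ½KL(q‖m)`, `m=(p+q)/2`,
  `0·log0 = 0`), averaged over spots; the base-2 choice caps it at 1.
* **Marker PCC** for when truth is unknown: per type, the Pearson
  correlation across spots between the estimated proportion column and the
  unweighted mean of the type's marker genes on depth-normalized spot
  counts. Types with a constant column are reported as undefined and
  excluded from the mean. The marker summarization (mean vs. sum, normalized
  vs. raw) is a convention of this package, recorded on every result object.

## Numerical choices and defaults

| parameter | default | notes |
|---|---|---|
| `learning_rate` | 0.1 | stable for normalized references; 0.01 with 10⁴ epochs is used in the solver-optimality tests on raw-scale instances |
| `num_epochs` | 1000 | exact iteration count, no early stopping |
| `ridge_lambda` | 0.1 (scalar) / `0…0.2` grid for CV | |
| `n_fold` | 5 | gene folds |
| `cellcount_min` | 2 | |
| `gene_top` | 200 | per-type markers before the union |
| simplex tolerance | 1e-9 | row-sum check on proportion containers |
| KKT/oracle tolerance | 1e-4 | solver-optimality tests |

Degenerate inputs: empty gene intersection, all-zero cells, all types rare,
fewer genes than folds, negative counts, duplicate gene ids and off-simplex
proportion rows all raise informative errors; degenerate spots fall back to
uniform rows as described above.

## Known limitations

* The fixed-step solver's stable learning-rate range depends on the scale of
  `X`; the default suits normalized references, and raw-count references may
  need a smaller step (the divergence error says so).
* Cross-validation cost is `|grid| × n_fold` full solver runs; on desk-scale
  data this is seconds to a minute, but it dominates the runtime of any
  workflow that uses it.
* Marker-gene PCC is a proxy metric: perfect proportionality between marker
  expression and composition holds only approximately in tissue data.
* Proportions are relative within a spot; absolute cell counts per spot are
  out of scope, as is any spatial-prior smoothing across neighboring spots.
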