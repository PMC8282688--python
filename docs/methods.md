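# Methods

## The model

`tracreg` predicts a continuous phenotype $y \in \mathbb{R}^n$ from a
sample-by-taxon table of amplicon read counts $X \in \mathbb{R}_+^{n\times p}$.
Read counts are compositional: the library size of a sample carries no
biological information, so only relative abundances may enter the model.
The classical answer is the sparse log-contrast regression

$$\min_\beta \tfrac{1}{2n}\lVert y - \log(X)\beta - b\mathbf{1}\rVert^2
  + \lambda \lVert\beta\rVert_1
  \quad\text{s.t.}\quad \mathbf{1}^\top\beta = 0 ,$$

whose zero-sum constraint makes predictions functions of log-ratios only and
hence invariant to per-sample rescaling.

The tree-aggregated estimator generalizes this by letting the taxonomy
$\mathcal{T}$ define candidate *aggregations*: requiring $\beta$ to be
constant on a subtree is the same as regressing on the log geometric mean of
the subtree's counts.  Collecting one feature per non-root node $u$,

$$Z_{iu} = \frac{1}{|L_u|}\sum_{j \in L_u} \log\!\big(X_{ij} + c\big),$$

with $L_u$ the subtree's leaf set and $c$ a pseudocount, the estimator solves

$$\min_{\alpha}\; \tfrac{1}{2n}\lVert y - Z\alpha - b\mathbf{1}\rVert^2
  + \lambda \sum_u w_u\,\lvert\alpha_u\rvert
  \quad\text{s.t.}\quad \mathbf{1}^\top\alpha = 0 ,
  \qquad w_u = |L_u|^{-a}.$$

A single nonzero $\alpha_u$ selects the whole subtree at $u$; the leaf-level
coefficients are recovered as $\beta = A\,\mathrm{diag}(1/|L_u|)\,\alpha$
with $A$ the binary leaf-by-node ancestry matrix, and satisfy
$\mathbf{1}^\top\beta = \mathbf{1}^\top\alpha = 0$.

### Parameters that matter

- **`a` (weight exponent, default 1).** Controls how cheaply large subtrees
  can be selected. `a = 1` is the standard setting and aggressively favors
  coarse aggregations; `a = 1/2` ("weighted") sits closer to the leaves; a
  strongly negative `a` (e.g. `-5`) prices every internal node out of the
  model and reproduces the leaf-only sparse log-contrast fit exactly.  `a`
  is a user choice, deliberately excluded from model selection.
- **`pseudocount` (default 1).** Added to *all* counts before the log so
  zero counts are defined.  A uniform additive constant preserves the
  equal-counts identity (all counts equal $c$ in a subtree give feature
  $\log c$).  With pseudocount 0 on strictly positive data the model is
  exactly scale-invariant; a nonzero pseudocount breaks exact invariance for
  real zero-laden data, which is the standard and unavoidable compromise.
- **`n_lambda` / `min_fraction` (defaults 50 and 1e-3).** Geometric grid
  from $\lambda_{\max}$ (the closed-form threshold where the all-zero
  solution stops being optimal) down to `min_fraction * lambda_max`.
- **Cross-validation (default 5-fold) with the one-standard-error rule.**
  The grid is computed once on the full training set and reused across
  folds; per-$\lambda$ fold MSEs give a mean curve and its standard error
  (SD of fold means / $\sqrt{k}$).  The default selection is the largest
  $\lambda$ within one SE of the minimum, which prefers sparser aggregation
  models; CV-best is available by flag.
- **Intercept.** Fitted unpenalized by centering $y$ and the columns of
  $Z$.  Responses in physical units need the location shift; the zero-sum
  structure is untouched.  Columns are *not* standardized: the
  $|L_u|^{-a}$ weights are the intended scaling mechanism and standardizing
  would distort their semantics.

## The solver

The optimization problem is a weighted lasso with a single linear equality
constraint.  The package solves it along the $\lambda$ grid with a
*certified active-set method*:

1. For a hypothesized support $S$ and sign vector $s$, the equality-
   constrained quadratic subproblem is solved exactly through its bordered
   KKT system $[Q_{SS}, \mathbf{1}; \mathbf{1}^\top, 0]$.
2. If a solved coefficient disagrees with its hypothesized sign, the step
   toward the new solution is truncated at the first zero crossing and that
   coordinate leaves the support (the classical nonnegative-least-squares
   step, which guarantees monotone progress).
3. Stationarity of the full problem is then checked by the KKT certificate:
   with $c = Z^\top(\tilde y - Z\alpha)/n$, the violation
   $\max_u \mathrm{dist}(c_u - \mu,\; \lambda w_u\,\partial|\alpha_u|)$ is
   minimized over the constraint multiplier $\mu$ (a 1-D convex
   piecewise-linear problem).  If the violation exceeds the tolerance, the
   worst violating coordinate enters the support with the sign of
   $c_u - \mu$.
4. A solution is accepted only when the certificate is below
   `1e-7 * max(1, ||Z'y/n||_inf)`; "iterations exhausted" is reported as a
   warning, never silently.  A small ADMM loop (splitting the smooth loss
   and constraint from the l1 prox) serves as a restart heuristic in the
   rare event the active set cycles on degenerate designs.

Warm starts across the geometric grid make the whole path cost a few exact
subproblem solves per grid point.  $\lambda_{\max}$ itself has the closed
form $\max_{u,v} (c_u - c_v)/(w_u + w_v)$, the 1-D weighted Chebyshev
center of the initial correlations.

**Duplicate columns.** A non-branching taxonomy chain (a rank level with a
single child) produces exactly identical feature columns, making the l1
solution non-unique.  The solver collapses each group of identical columns
to one representative — the member with the smallest penalty weight,
breaking exact ties toward the deepest node — and reports the coefficient
there; `column_dedup_report` makes the degeneracy visible.

**Structural collinearity.** Every internal node's feature is exactly the
leaf-count-weighted mean of its children's features, so the quadratic form
is always rank-deficient; uniqueness of the optimum comes from the penalty.
In the ultra-dense regime (very small $\lambda$, support comparable to the
column count) ties between a node and its own leaves can appear: fitted
values and the objective remain unique but individual coefficients are not
identified there.  All invariance checks on coefficients therefore operate
on the sparse part of the path (`min_fraction = 1e-2`), which is also the
regime cross-validation selects in practice.

## The synthetic-data generator

`simulate` produces data with the shape of amplicon surveys:

- **Taxonomy**: a seeded random recursive partition of the leaves across the
  configured ranks (leaves shuffled once, blocks split into near-equal
  chunks with a configurable branching range).
- **Counts**: each leaf gets a baseline log-abundance (`mean_spread`, SD of
  the per-leaf baselines, default 1); per sample, independent Gaussian noise
  on the log scale (`overdispersion`, default 1) perturbs the latents; the
  softmax gives the sample's composition; reads are a multinomial draw of a
  Poisson(`depth_mean`, default 10,000) library size.  Zeros arise naturally
  for rare taxa.  The log-normal/multinomial construction was chosen over a
  Dirichlet-multinomial to control per-leaf overdispersion directly.
- **Response**: $y = \sum_u \alpha_u Z_u + \varepsilon$ for a configured
  zero-sum support over tree nodes, so the ground truth lies exactly in the
  estimator's feasible set.

What it does **not** emulate: phylogenetic depth structure, batch effects,
taxon-taxon ecological interactions, and the heavy-tailed abundance
distributions of real surveys.  Passing recovery tests on these simulations
demonstrates correctness of the estimator and selection machinery, not
field performance on real microbiome data.

### The reference recovery scenario

`default_scenario` is the package's benchmark for support recovery: n = 200
samples, p = 50 OTUs arranged in ten genera of five, and a ground-truth
log-ratio contrast of +2 / -2 between two randomly chosen genera, with
response noise at 10% of the signal SD.  The packaged 50-replicate
reference run (seeds 0-49) recovers exactly the two true genera in 47 of
50 replicates.  The recovery probability is knife-edge sensitive to where
the cross-validated 1SE lambda lands relative to the noise floor of an
inactive genus's stationarity bound, so rates measured on other replicate
sets are somewhat lower (roughly 80-90%); the typical failure adds a single
spurious genus with a small coefficient rather than missing a true one.

The taxonomy of this scenario is deliberately *shallow*.  Two structural
mechanisms, interesting in their own right, make exact support recovery
unattainable under deeper taxonomies:

1. **Saturated ancestors.** Because a parent's feature is the
   leaf-count-weighted mean of its children's and $w_u = 1/|L_u|$, the
   stationarity bound of the parent of a single active child is *exactly*
   saturated by that child's contribution at any optimum.  Whether the
   parent enters is decided by the (mean-zero) contributions of its inactive
   children — effectively a coin flip per ancestor.
2. **Cheap coarse nodes as constraint slack.** A near-constant, very
   low-weight column (a node covering much of the dataset) can absorb the
   small imbalance that shrinkage induces between the two active
   coefficients at a penalty cost of order $\lambda|L|^{-1}$, and its KKT
   bound is small enough that noise-floor correlations
   ($\sim \sigma_\varepsilon\,\mathrm{sd}(Z_u)/\sqrt{n}$) cross it.

Both mechanisms mirror the estimator's real-data behavior (coarse clades
appearing alongside specific ones in selected models); they are properties
of the $|L_u|^{-a}$ weighting, not solver artifacts.  When the candidate
aggregations all price equally — as in the reference scenario — the
estimator identifies the true pair reliably.

## Numerical conventions

- Support rule: $|\alpha_u| > 10^{-8}\max(1, \lVert\alpha\rVert_\infty)$
  counts as selected.
- Feasibility: every returned $\alpha$ satisfies
  $|\mathbf{1}^\top\alpha| \le 10^{-8}$ (the active-set solve projects the
  restricted solution onto the constraint exactly).
- Pearson correlation of a degenerate (zero-variance) prediction vector is
  reported as NaN, never raised.
- Benchmark summaries round mean sparsity half-to-even; train size in
  repeated splits is `round(train_fraction * n)`.
- Fold assignment and split plans are pure functions of their seeds; every
  CLI output is accompanied by the resolved configuration for provenance.

## Known limitations

- Squared-error loss only; no classification losses, non-compositional
  covariates, or confidence intervals / post-selection inference.
- Taxonomic trees only (rank lineages); no branch-length phylogenies.
- Exact numeric reproduction of results from other implementations would
  require matching their zero-replacement rule and $\lambda$ grid, neither
  of which is standardized.
- Coefficient non-uniqueness in the ultra-dense regime (see above) is
  inherent to the feature construction, not resolvable by the solver.
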