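# Methods

## The decomposition

Each gene's log10 expression over a complete organ × species grid is treated
as a balanced two-factor layout without replication. The additive model

    y_ij = μ + org_i + spc_j + ε_ij

admits an exact orthogonal split of the total sum of squares about the
grand mean into organ, species, and residual terms (SST = SSO + SSS + SSR).
Because the design is balanced, the split does not depend on factor order
and requires no iterative fitting; the grand mean is the arithmetic mean of
all n_o·n_s values. There is no replication within a cell, so any
organ × species interaction is inseparable from noise and lands in SSR —
the model deliberately has no interaction term. Genes with zero total
variance have undefined proportions; they are flagged (NaN) and excluded
from mean summaries, with the excluded count reported separately.

No significance testing is attached to the decomposition: the quantities of
interest are the variance proportions themselves, not rejection of a null.
A random-effects (REML) formulation of the same two factors yields nearly
identical relative contributions while requiring an estimation step, so the
fixed-effect closed form is used throughout.

## Classification thresholds

* `dr_min = 2` — dynamic range in orders of magnitude,
  log10(max + 0.01) − log10(min + 0.01) on linear-scale values. Genes below
  it are *constrained*: their expression varies so little that the split of
  that variance is not biologically meaningful.
* `explained_min = 0.75` — a gene must have p_o + p_s ≥ 0.75 to be called
  factor-dominated at all.
* `fold = 2` — dominance of one proportion over the other
  (p_o ≥ 2·p_s → TVG, p_s ≥ 2·p_o → SVG).

All comparisons are inclusive (≥), matching the "at least" reading of each
rule; a strict mode is available via `ClassificationThresholds(inclusive=False)`.
The classifier also exposes the pre-intersection dominance masks (≥ 75%
explained and fold-dominant, ignoring dynamic range), since both the
filtered and unfiltered counts are of interest.

## Factor-variance cancellation

`remove_factor_variance(mat, "organ")` centers and scales each gene within
each organ across species, which forces SSO = 0 in a re-decomposition;
`"species"` is symmetric. The direction convention is: scaling *within each
level of a factor* cancels *that factor's* variance. Groups with zero
standard deviation are mapped to zeros (not NaN) so PCA and decomposition
stay defined. The pairwise human-vs-other decomposition standardizes each
sample (column) to mean 0, sd 1 before decomposing each gene on the
2-species submatrix.

## Modularity

Networks are built by strict thresholding (corr > t) of the between-sample
Pearson correlation matrix computed on all genes' log values, with the
diagonal of the adjacency set to 0. Q is evaluated by the pairwise Newman
form over all ordered node pairs, including i = j, where only the null-model
term contributes. The curve is parameterized by target edge counts rather
than thresholds: the threshold for e edges is placed between the e-th and
(e+1)-th largest off-diagonal correlations, so the achieved count is exact
up to ties (ties yield the nearest achievable count, which is reported).
Isolated nodes stay in the network and contribute through the null model
only. Q on the complete graph is computable but carries no thresholding
information (every grouping gives Q ≈ 0), so dominance comparisons should
use sub-complete densities.

## Projection score

Subsets are nested by per-gene variance as a fraction of the maximum gene
variance (default grid: 30 log-spaced ratios in [1e-4, 1]; subsets smaller
than d+1 genes are dropped). For a subset, alpha is the square root of the
fraction of total variance captured by the first d principal components of
the gene-standardized submatrix (centered and scaled by default; a
center-only mode exists). The null shuffles each gene's values across
samples independently — destroying sample structure, preserving gene
marginals — with fresh permutations per subset from a single seeded
generator; the score is observed alpha minus the null mean (default
n_perm = 100, d = 3).

Selection: scores of two subsets differ only through independent
Monte-Carlo estimates of their null means, so differences below the
standard error of that difference are not resolvable; all subsets within
one such SE of the maximum are treated as tied and the largest tied subset
is returned. This biases selection mildly toward larger subsets, which is
the conservative direction for downstream PCA.

## Clustering and PCA

Hierarchical clustering is complete-linkage on 1 − |r| distances between
samples' correlation-vector profiles (each sample represented by its row of
the sample-correlation matrix); a Euclidean mode on raw log values is also
provided. The 1 − |r| form maps strong anticorrelation to small distance;
it is implemented as stated, with a 1 − r option. PCA standardizes each
gene across samples and uses a plain SVD; component signs are fixed so the
largest-magnitude loading is positive. Constant genes are dropped with a
warning when scaling.

## The simulator

The generator emulates a balanced multi-species organ panel: per gene,
organ effects are i.i.d. Normal(0, σ²_o); species effects are either i.i.d.
Normal(0, σ²_s) or Brownian motion along a phylogeny; residuals are i.i.d.
Normal(0, σ²_e). Phylogenetic effects use the correlation implied by shared
root-to-tip branch length, R_ab = L_shared / √(L_a L_b), scaled by σ²_s, so
every tip has the same marginal variance regardless of root-to-tip depth.
The default tree covers human, chimpanzee, rhesus, mouse, opossum,
platypus, and chicken with round consensus divergence times (6, 29, 90,
160, 180, 300 My splits); the qualitative consequence — the organ share of
a pairwise reference-vs-other decomposition declines with distance — does
not depend on the exact lengths.

Genes are drawn from a four-class mixture: TVG-like (σ²_o ∈ [1, 4],
σ²_s ∈ [0, 0.2]), SVG-like (mirrored), balanced (both ∈ [0.5, 1]), and
constrained (all ∈ [0, 0.01]); residual σ²_e ∈ [0.01, 0.05] except
constrained ([0, 0.01]). These ranges put TVG/SVG genes cleanly past the
2-order dynamic-range and 75%-explained thresholds. The baseline
μ ∈ [1, 4] (10–10⁴ cRPKM) keeps genes in the expressed regime, so clipping
at zero on the linear scale (values are emitted as max(0, 10^y − 0.01))
affects well under 1% of entries and does not distort the variance
structure; the exact-recovery flag `emit_log=True` bypasses the linear
round trip for tests that need bit-level control.

What the simulator does *not* emulate: count-level (negative-binomial)
noise, mean–variance coupling, inter-individual variation, batch structure,
or correlated gene modules beyond what the shared factors induce. Passing
tests therefore demonstrate correctness of the estimators and the
qualitative factor-dominance logic, not robustness to those real-data
features.

## Problem sizes and numerical choices

Test and acceptance runs use 300–5000 genes on the 6 × 7 design — large
enough that pooled sums of squares are within ~1% of their expectations
while the whole suite stays fast. The calibrated recovery scenario
(σ²_o, σ²_s, σ²_e) = (4, 1, 0.25) has closed-form expected sums of squares
E[SSO] = (n_o−1)(n_s σ²_o + σ²_e) = 141.25, E[SSS] = (n_s−1)(n_o σ²_s +
σ²_e) = 37.5, E[SSR] = (n_o−1)(n_s−1) σ²_e = 7.5, i.e. pooled shares
(0.758, 0.201, 0.040). The *pooled* ratio (sum of SS over genes) is used
for this comparison because the per-gene ratio p_o is a ratio of correlated
chi-square variables whose mean is biased away from the ratio of
expectations at these small design sizes (≈0.71 vs 0.758 for the organ
share); the pooled estimator is consistent for the stated quantity.
Likewise, rank-correlation recovery is measured against the truth table's
realized per-gene variance fractions (computed from the sampled effect
vectors), which is the quantity the decomposition estimates; correlation
with the population σ-shares is additionally capped (~0.94) by the sampling
noise of a 6 × 7 grid itself.

Sum-of-squares conservation holds to ~1e-13 relative; tests assert 1e-9.
Cholesky factorization of the tree correlation adds a 1e-12 jitter to guard
exactly singular matrices. Zero-variance scaling groups map to zeros;
zero-variance genes propagate NaN proportions and classify as constrained
(their dynamic range is 0).
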