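# Methods

## Overview

`sdcornet` builds an unweighted gene coexpression network from an m × n
expression matrix M (genes × samples) in three stages:

1. **Preprocessing** — per-sample low-expression masking followed by
   quantile normalization, yielding M*.
2. **Association** — the signed distance correlation matrix S (with
   Pearson, Spearman and mutual-information comparators).
3. **Thresholding** — a hard threshold θ chosen to maximize a
   resampling-based self-consistency score; genes i ≠ j are connected iff
   S[i, j] ≥ θ.

Networks can then be summarized topologically and scored against
STRING-style interaction evidence.

## Preprocessing

Within each sample (column), the ⌊f·m⌋ smallest values are flagged as
unreliable (default f = 0.2; ties at the cutoff broken by row order so the
count is exact and deterministic). The remaining values are
quantile-normalized: every column's sorted unmasked values are replaced by
the rank-wise mean across columns, so all columns share one empirical
distribution. Tied raw values receive the mean of the reference values of
their tied ranks (the standard convention). Finally the masked entries are
set to the global minimum of the **raw** matrix, flooring unreliable
measurements to one common low value.

By default only unmasked entries enter the normalization; the alternative
(normalize everything, then floor) is available via
`preprocess(..., normalize_unmasked_only=False)`.

Flooring has a side effect documented under *Limitations*: it imprints a
shared low-value pattern across genes that are low in the same samples,
and can force a systematic Pearson sign onto non-monotone gene pairs.

## Signed distance correlation

For gene i with expression vector x, the n × n expression distance matrix
has entries |x_h − x_k|. Double-centering (subtract row and column means,
add the grand mean) gives the centered profile Y(i) with vanishing row and
column sums. The distance covariance of genes i, j is

    dcov(i, j) = (1/n) · ( Σ_{h,k} Y(i)_{h,k} · Y(j)_{h,k} )^{1/2}

and the distance correlation is dcor(i, j) = dcov(i, j) /
√(dcov(i, i)·dcov(j, j)) — equivalently, the non-negative square root of
the Pearson correlation between the flattened centered profiles (they are
zero-mean, so cosine similarity and Pearson coincide; the 1/n factor
cancels). dcor ∈ [0, 1], is zero iff the vectors are empirically
independent in the distance sense, and responds to nonlinear as well as
linear dependence. It is invariant to shifting a gene's vector and to
scaling it by any nonzero constant.

Because dcor is sign-free, the **signed** distance correlation multiplies
it by the sign of the ordinary Pearson correlation of the same pair:
S = sign(P)·D, with sign(0) = 0 (such pairs can never pass a positive
threshold). |S| = D entrywise, and S flips sign when exactly one gene
vector is negated.

Computation is blocked over gene chunks (default 256 genes), keeping the
memory of the flattened profiles at O(block · n²); results are independent
of the block size. Genes with zero distance variance (constant rows, e.g.
fully floored genes) get all correlations set to 0 with a warning rather
than raising mid-pipeline.

## Comparators

- **Pearson / Spearman** — row-wise, Spearman as Pearson on average ranks.
  Constant rows are zeroed with a warning.
- **Mutual information** — each gene's vector is discretized into
  equal-frequency bins (ties split by sample order so every bin holds
  ⌊n/b⌋ or ⌈n/b⌉ observations); MI is the plug-in estimate (natural log)
  from the joint histogram. The bin count defaults to ⌊√n⌋. Using b = n is
  supported but degenerate — one observation per bin makes every marginal
  uniform and every pair score the identical maximum log n, so the matrix
  carries no ranking information; the default sublinear count is what an
  empirical-entropy estimator needs at these sample sizes.

## Threshold selection by self-consistency

A good threshold should produce networks that are stable under resampling
of the samples. For each of R repetitions (default 25):

- Draw two overlapping column subsets of size ⌊3n/4⌋ sharing ⌊n/2⌋
  uniformly chosen samples (so roughly a third of each subset differs;
  both fractions are configurable). For n = 54 this gives two 40-column
  matrices sharing 27 columns.
- Preprocess each submatrix independently (configurable: a variant slices
  the preprocessed full matrix instead) and compute the chosen correlation
  matrix for each.
- For every θ in the grid (default 0.00–0.99, step 0.01), threshold both
  matrices and record the corrected edge similarity of the two networks.

The corrected similarity of networks G1, G2 on a common node set is

    sim(G1, G2) = (|E1 ∩ E2| − β) / (|E1 ∪ E2| + β)

where β is the overlap expected if both were configuration-type random
graphs: the degree sequences are randomly permuted over the node set, and

    β = |E1| · Σ_{(u,v)∈E1} d2*(u)d2*(v) / Σ_{u} Σ_{v≠u} d2*(u)d2*(v)
      + |E2| · Σ_{(u,v)∈E2} d1*(u)d1*(v) / Σ_{u} Σ_{v≠u} d1*(u)d1*(v).

The denominators run over **ordered** node pairs. This choice matters:
it caps each directional term at |E_i|/2 and hence β at (|E1|+|E2|)/2,
which is exactly what guarantees sim ∈ [−1/3, 1] for *every* graph pair
(with an unordered denominator, unbalanced pairs can fall below −1/3).
For equal edge counts, β is then the average of the two directional
configuration-model expected overlaps — i.e. literally "the expected edge
overlap if the graphs were random". Identical complete graphs score 0:
a complete graph is indistinguishable from its own degree randomization.
An alternative that averages (rather than sums) the two directional terms
is exposed as `halve_beta`. Each similarity evaluation draws a fresh
degree permutation; one RNG stream per repetition (spawned from the master
seed) makes the whole profile bit-reproducible.

Averaging over repetitions gives s(θ); the score balances stability
against density:

    Score(θ) = s(θ) − density(full-data network at θ)

with the density always taken from the network built on the complete
preprocessed matrix. The selected θ* maximizes Score; ties break toward
the larger θ (sparser network). Repetition/θ combinations where both split
networks are empty contribute similarity 0 and are reported in a warning.

**Operating regime.** The β correction makes the score intrinsically
favor sparse structure: a dense clustered network is close to its own
configuration randomization, so its corrected similarity — and hence its
score — collapses no matter how reproducible it is. The score is therefore
informative when true structure occupies a small fraction of all gene
pairs (a percent or two, as in real transcriptomes), and that is the
regime the synthetic defaults emulate.

## Density matching and topology

To compare methods fairly, each correlation matrix can be thresholded to
reproduce another network's edge density: the threshold is set to the
value reaching the target edge count, with the full tie class at the
cutoff included (mutual information matrices tie heavily, so the achieved
count can overshoot; the overshoot is reported). The pipeline builds the
full grid of native and density-matched networks across methods; a
`dedupe_density_tol` option collapses near-identical native densities.

Topology summaries report edge count, density, and the size, density and
global clustering coefficient of the largest connected component. The
clustering coefficient is transitivity — 3 × triangles / connected triples
— not the mean local coefficient. Isolated nodes are never dropped: every
network keeps the full gene set as its node set.

## Interaction-evidence evaluation

STRING-style tables carry integer channel scores in [0, 1000] per
unordered pair. Channels are combined with the standard STRING rule: scale
to [0, 1], remove the random-interaction prior p from each channel
((s − p)/(1 − p), floored at 0), combine as 1 − Π(1 − s_i), re-add the
prior, rescale. The default prior is 0.041 (configurable). If no included
channel carries evidence the result is 0 — the prior is not re-added to
non-evidence, so an all-zero record scores 0 and single-channel tables
pass through unchanged.

Three selections are evaluated: all channels (C_total), only the
coexpression and coexpression-transferred channels (C_coexpression_only),
and everything except those two (C_no_coexpression). A network's aggregate
score is the sum of combined edge scores divided by the number of edges;
edges absent from the table count 0 in the numerator but still appear in
the denominator. Baselines are 30 (configurable) uniform random edge sets
of the matching edge count on the same node set; fold enrichment is the
aggregate score over the baseline mean.

## Synthetic data

The generator emulates the statistical structure the method assumes. Each
module k has a latent profile z_k, i.i.d. standard normal across samples.
Member genes are linear (z_k + ε), anti-correlated (−z_k + ε) or nonlinear
(the standardized square of the centered profile, plus ε) with
ε ~ N(0, noise_sd²); background genes are i.i.d. standard normal. A truth
table records exactly the within-module pairs. The paired interaction
generator gives true pairs a high score and a chosen fraction of non-pairs
a low score, in a single "combined" channel.

Defaults — the conditions under which the package's claims are tested —
are 2 modules × 20 genes, 160 background genes, 50 samples, noise_sd 0.1,
no anti or nonlinear genes. With 160 background genes the 380 true pairs
are 1.9% of all pairs, matching the sparse regime discussed above (the
reference analyses select densities of 1.25–1.65%); with the modules
dominating the gene set the self-consistency score would correctly refuse
to endorse any threshold, which is a property of the score, not a failure
of the generator.

What the generator does **not** emulate: mean–variance relationships and
count noise of sequencing data, gene-specific baseline expression levels,
overlapping or hierarchical modules, and batch structure. Passing the
recovery tests therefore shows that the machinery identifies clean,
disjoint, sparse modules under Gaussian noise — not that it handles every
real-data pathology.

## Numerical choices and degenerate inputs

- Thresholding uses ≥, so pairs exactly at θ are edges.
- Masking counts are exact per column: ⌊f·m⌋, stable-sorted.
- sign(0) = 0 in S; such pairs never pass a positive threshold.
- Constant gene rows correlate 0 everywhere (warning), never an exception.
- Correlation matrices are symmetrized ((C + Cᵀ)/2) against float drift
  and validated symmetric to 1e-12.
- All randomness flows through explicitly passed NumPy generators or seed
  sequences; no global RNG state is touched. Fixed seeds give
  bit-identical profiles, networks and output files.
- Distance-correlation inner products are clipped at 0 before the square
  root (they are mathematically non-negative; tiny negative float residues
  occur).

## Problem sizes

The shipped tests and the acceptance script run the full machinery on
200-gene, 50-sample studies with 25 repetitions over the 100-point θ grid
(seconds on one core). The implementation itself is blocked and vectorized
so the same code handles genome-scale matrices (thousands of genes); the
θ sweep then dominates the cost and scales linearly in repetitions × grid
size × gene pairs.

## Limitations

- **Sign loss for non-monotone and anti-correlated pairs.** A positive
  threshold on S keeps only positively-signed associations. Anti-correlated
  within-module pairs (S ≈ −D) and symmetric nonlinear pairs whose Pearson
  sign is essentially the sample skewness of the latent profile are
  invisible to the selected network. The unsigned D matrix retains them at
  the cost of direction information.
- **Flooring imprints structure.** Setting masked entries to the global
  minimum creates a shared pattern among genes that are low together and
  systematically pushes the Pearson sign of quadratic-vs-linear pairs
  negative (the floor is hit where the linear partner is low but the
  quadratic gene is high). The nonlinear-recovery analyses therefore run
  with masking off.
- **Score favors sparsity.** See *Operating regime*: dense true structure
  cannot win under the β-corrected score.
- **MI thresholds tie heavily.** Density matching on MI matrices
  overshoots edge counts; the tie class is included by design.
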