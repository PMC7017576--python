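# Methods

This note records the models implemented in `footprintbench`, the defaults
and why they were chosen, and the numerical conventions that matter when
comparing results.

## Gene-set resources

A **regulon network** is a table of signed TF→target edges with an
interaction likelihood in (0, 1] (defaulting to 1 when absent) and a curated
confidence grade A–E (A most reliable, defaulting to E when absent). A TF's
summary confidence is the supplied per-TF grade when the resource provides
one, otherwise the best grade among its edges — so confidence-combination
subsetting ("AB" etc.) acts at TF level. Before scoring, TFs with fewer than
4 targets among the measured genes are discarded; the pruning keeps edges to
unmeasured genes because each scorer intersects with its signature again.

A **footprint model** maps each pathway to weighted genes ordered by a
responsiveness rank (1 = most responsive to perturbation of that pathway).
Subsetting to the top N ranks trades specificity (small, most-responsive
footprints) against robustness to low gene coverage (large footprints keep
more measured genes in play).

Gene identifiers are opaque case-sensitive strings throughout; no identifier
mapping is attempted.

## Activity statistics

**Footprint score.** For signature s and pathway p,
`score(p, s) = Σ_{g ∈ footprint(p) ∩ genes(s)} weight(p,g)·s(g)`, i.e. a
linear model in the signature. With `scale=True` (the default) each pathway
row is standardized to mean 0, sd 1 (sample sd) across columns; rows with
zero spread are dropped with a warning.

**Regulon NES.** Genes are ranked by signature value (average ranks on
ties) and mapped to standard-normal quantiles `q_g = Φ⁻¹(rank_g/(n+1))`;
then `NES(tf) = Σ mode·likelihood·q_g / √(Σ likelihood²)` over the measured
targets. Under an exchangeable signature the statistic is asymptotically
standard normal, which makes scores comparable across regulon sizes — the
normality contract the downstream benchmark relies on. This analytic form
replaces the two-tailed/one-tailed aREA combination of the original
enriched-regulon framework: the benchmark consumes only NES rankings, and
the analytic statistic preserves the null contract while removing the
pleiotropy-correction machinery that is out of scope here. Tests verify it
against a 10,000-shuffle permutation null (agreement within 0.15 on 50-gene
signatures). Single-sample matrices are gene-wise standardized (mean 0,
sd 1 per gene across cells) before ranking; contrast matrices of logFCs are
scored as-is.

**Consensus NES.** With several networks (e.g. tissue-specific regulons),
per-network NES values are integrated per TF as the squared-NES
self-weighted average `Σ NESₖ³ / Σ NESₖ²` over the networks reporting the
TF. The rule favours networks making confident (large-magnitude) calls in
either direction, reduces to the identity for one network, and returns 0
when every vote is 0. The integration rule is a package design choice
(exposed, documented) since consensus integration admits several reasonable
conventions.

**Recovery-curve AUC.** Per cell, genes are sorted by decreasing raw count,
with ties broken by input row order — a fixed, seed-independent rule. With
`k = ceil(quantile·n_genes)` (quantile default 0.05), the score is the area
under the step curve of cumulative gene-set hits over ranks 1..k, divided by
the maximum attainable area (all `min(|set|, k)` members at the top), so
scores lie in [0, 1] with 1 attainable. Modes, likelihoods and footprint
weights are deliberately ignored — this statistic is rank-only — and scores
are invariant to any monotone transform of a cell's counts.

**Permutation GSEA.** The enrichment score is the signed maximum deviation
from zero of the weighted Kolmogorov–Smirnov running sum with weight
exponent 1 (hit steps `|logFC|/Σ|logFC|` over members, miss steps
`1/(n − m)`; a set spanning the whole universe has no miss steps). The null
is `n_permutations` (default 1000) gene-label shuffles; NES divides ES by
the mean |ES| of same-sign permutations and p is the same-sign tail fraction
with add-one smoothing. No multiple-testing adjustment is applied — the
benchmark consumes raw scores.

## Bulk → single-cell simulation

From a bulk count vector C (optionally with gene lengths; without them TPM
reduces to CPM), `B = TPM(C)` and `P = B/ΣB` give per-gene sampling
probabilities. A cell's library size L is drawn from Normal(μ, sd = μ/2) —
the second parameter is read as a standard deviation, giving a constant
coefficient of variation of ½ across the μ grid — rounded and truncated
below at 0. The cell's counts are one multinomial(L, P) draw, which is
distributionally identical to L with-replacement draws but faster. Cells
with total counts strictly below 100 are discarded (truncated-to-zero
libraries fall out here). Expected drop-out of gene g at library L is
`(1 − P_g)^L`, verified empirically in tests, and detected genes per cell
grow monotonically with L.

Normalization is a size-factor log-normalization: size factor = library
size / geometric-mean library size, value = log2(count/sf + 1). The
pooling/deconvolution normalization used with real single-cell data is not
reimplemented; downstream benchmarks consume group-mean contrasts, which
are insensitive to this choice.

The model simulates a homogeneous population per bulk sample; mixtures are
composed from several mean profiles (synthdata). Real-data artifacts it
does **not** emulate: ambient RNA, doublets, batch effects, UMI saturation,
transcript-length bias within a protocol. Passing benchmarks on these
simulations therefore speak to information loss from sparsity and library
size, not to protocol-specific noise.

## Perturbation-recovery benchmark

Contrasts are perturbed-minus-control means of normalized log expression
(or of activity scores, feature-wise). A moderated differential-expression
fit is deliberately not used: only logFCs feed downstream, and the
coverage-masking logic requires exact zeros to encode "not covered".
Coverage masking zeroes uniformly random positions per contrast and
replicate (default 25 replicates) until exactly the target number of nonzero
entries remains; surviving values are never altered. Knockdown QC drops
direction = −1 records whose target's own logFC is > 0 (strict; unmeasured
targets are kept with a warning).

For evaluation, scores of inhibition/knockdown contrasts are multiplied by
−1 so the perturbed feature should rank highest; the perturbed feature's
score in its own contrast is the positive class and all other
feature–contrast scores are negative. AUROC is trapezoidal (equal to
pairwise concordance with ties counted ½, verified against a brute-force
oracle); AUPRC is step-integrated average precision. Contrasts whose target
is not covered by the gene-set resource are excluded from scoring but
reported, and TF coverage (distinct perturbed features actually scored) is
part of every result, making the coverage/performance trade-off explicit.
Grid summaries average per-replicate AUROCs (not pooled curve points) and
report mean single-cell-minus-bulk differences per grid cell.

## Cluster purity

HVG selection follows the vst recipe: per-gene variance is regressed on
mean (both log10, lowess with span 0.3) on raw counts; observations are
standardized by the fitted sd, clipped at √n_cells, and genes are ranked by
the variance of the standardized values (default top 2000). The positive
control is the top-n HVG expression matrix and the negative control a
seeded random n-subset of the top 2000, so controls match the activity
matrix's feature count (14 for pathways, 113 for TFs in the motivating
setting).

Embedding is UMAP to 2-D with a fixed seed (single-threaded, deterministic).
Silhouette widths are computed on Euclidean distances in the embedded
space — the evaluation asks how well cell types separate in the
low-dimensional view the analyst actually inspects — with
`s = (b−a)/max(a,b)`; cells in singleton clusters are assigned s = 0 (a
common convention; the definition is silent there). Global purity is the
unweighted mean of per-cluster mean widths (the cell-weighted mean is also
reported, unweighted is primary). The bundled 5-level hierarchy spans
level 0 (each of 8 PBMC/HEK types distinct) to level 4 (PBMC vs cell line).
Statistical post-processing of purity tables (linear models, ANOVA,
post-hoc tests) is out of scope; the tidy tables such tests consume are the
output.

## Synthetic data and study conditions

The generators exist so every stage tests against known ground truth
offline. Bulk counts are negative binomial (gamma–Poisson,
var = m + φm²) with per-gene lognormal baseline means around
`baseline_mean = 50` and dispersion φ = 0.2 — standard overdispersed
RNA-seq magnitudes. A perturbation multiplies each direct target's mean by
`2^(effect·mode·direction)`; effects do not propagate beyond direct
targets, keeping the recovery ground truth unambiguous. Default study
conditions: 2000 genes, 20 TFs with 25 targets each, activating fraction
0.75, effect 2 (4-fold on direct targets), 30 experiments, half
inhibitory, 3 samples per group. The single-cell benchmarks run at μ = 5000
and 10 cells per bulk sample — a low but realistic sequencing depth and a
cell count at which information loss from the bulk template is visible.
The coverage-masking and footprint-size analyses use 10,000-gene compendia
so that the full coverage grid down from 8000 covered genes is realizable,
with footprints of 500 genes per pathway for the footprint-size comparison.

Nothing in the generators mimics real biological network topology or any
specific dataset's moments; they reproduce the *statistical structure* the
pipeline assumes (signed sparse regulons, overdispersed counts, directed
shifts, mixture populations), which is what the calibration and recovery
properties require.

## Numerical conventions and limitations

- Sample sd (ddof = 1) everywhere a scale is estimated; constant rows are
  zeroed (gene scaling) or dropped (activity scaling) with warnings.
- Ranking ties: average ranks for the NES statistic; stable input order for
  the recovery-curve AUC.
- All stochastic steps (library draws, multinomial sampling, masking,
  permutation nulls, negative controls, embeddings) take explicit seeds and
  are reproducible; replicate seeds are recorded in result metadata.
- The analytic NES is asymptotically normal; for very small signatures
  (tens of genes) its null is mildly discrete, which is why the permutation
  cross-check uses a 0.15 tolerance.
- The recovery benchmark assumes each experiment perturbs exactly one
  feature; combinatorial perturbations are out of scope.
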