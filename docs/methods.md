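# Methods

This note documents the models and procedures implemented in `coexflux`,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Variation statistics

**Variation score (development).** Profiles are normalized by total
expression over timepoints before any comparison, which makes the score
invariant to the overall expression level of a gene; only profile *shape*
matters. The reference envelope is the per-timepoint mean ± SD of the
normalized profiles of a supplied flat-gene set (the flat cluster is an
input, not something the package re-derives). The envelope is closed:
points exactly on μ_i ± σ_i contribute d_i = 0. The highly-variant
threshold is the 0.97 quantile (linear interpolation between order
statistics) of the flat genes' own VS values, so ≥ 97% of flat genes sit
below it by construction; the threshold is inclusive (VS equal to it counts
as highly variant).

**Coefficient of variation (tissues, compendium).** CV = σ/μ with the
*population* SD convention (divide by n). One SD convention is used
everywhere in the package — envelope, z-scores, CV — so downstream
thresholds are interpreted consistently. Tissue bands: invariant < 0.3 ≤
moderate < 0.75 ≤ high. Compendium rules: highly variant requires CV ≥ 0.75
in at least 3 member datasets; invariant requires CV < 0.3 in at least 95%
of the datasets *where the gene is present* — a gene absent from a dataset
is treated as lowly expressed there and excluded from the denominator. A
gene absent everywhere is lowly expressed outright.

**Low-expression filters.** The developmental filter fits a two-component
Gaussian mixture (EM, 10 k-means restarts, 500 iterations, tol 1e-6,
seeded) to the per-gene mean log2 expression; the threshold is
μ_low + σ_low of the lower component (the low-expression subpopulation,
LES) and a gene survives if it exceeds the threshold at ≥ 1 timepoint. Note
the threshold sits *inside* the low component by definition, so roughly
Φ(1) ≈ 84% of LES-population genes are removed — the filter bounds false
fluctuation, it does not classify the mixture. The tissue filter keeps
genes labeled moderate or high in ≥ 1 tissue; level labels are within-tissue
quantile cuts (rare < 50th pct < low < 70th < moderate < 90th < high),
an explicit convention since the labels are inherited from upstream data
in real use.

## Compendium assembly

Member datasets need ≥ 10 conditions. Each dataset is screened for
two-batch composition before normalization: gene rows are z-scored within
the dataset and the median |Pearson correlation| over condition pairs is
compared with a threshold of 0.5. The absolute value matters: with two
batches of similar size, between-batch condition pairs are strongly
*negative* after gene centering while within-batch pairs are strongly
positive, so a signed median hovers near zero exactly in the cases the
screen must catch. Flagged datasets are bipartitioned by a 2-cluster
average-linkage cut of the condition-correlation dissimilarity; the split
is accepted only if both halves have ≥ 2 conditions and fall below the
threshold after re-scoring (each half re-centered gene-wise), otherwise the
dataset is discarded as unexplained. Clean factor-model data trips the
screen in < 5% of seeded replicates at these settings.

Surviving datasets are z-normalized gene-wise (population SD; zero-variance
genes become all-NaN rather than zero — a constant gene carries no
correlation information and zeros would fabricate some) and concatenated
over the union gene set with NaN for genes absent from a member dataset.
Coexpression is pairwise-complete Pearson correlation over all compendium
columns; entries supported by fewer than `min_overlap = 10` shared
conditions are left missing.

## Coflux

For each ordered reaction pair (i, j), coflux is the relative drop of i's
flux capacity when j is constrained to zero, computed by linear programming
under steady-state mass balance and bounds (cobrapy/GLPK). Directions are
read from bounds, not flags: forward capacity is probed when ub > 0,
reverse when lb < 0. The reverse-direction ratio is
(v_min,i − v_min,ij)/v_min,i — both terms negative, so the ratio is
positive when the knockout shrinks reverse capacity — and enters the
direction combination as an absolute value. Pairs symmetrize by the max.
Values are clamped to [0, 1] (tolerance guards: fluxes below
`activity_tol = 1e-6` count as zero; the diet-amendment postcondition
guarantees the denominators exceed the tolerance).

**Redundant pairs.** When the knocked-out reaction j has a designated
cofactor-redundant twin (e.g. NAD- vs NADP-coupled versions of the same
conversion), the twin is constrained to zero as well; otherwise the twin
silently carries the flux and the dependency is invisible. The
co-constraint is applied to the *knocked-out* reaction's partner by
default — that is the reading under which the rule serves its stated
purpose of preventing bypass — with the alternative (partner of the
measured reaction i) available via `redundant_on="i"`. Redundant pairs are
model inputs; the synthetic `redundant_pair` topology ships one NAD/NADP
twin pair.

**Diet amendment.** Starting from the model's configured exchange bounds,
closed uptake exchanges are opened greedily — each step opens the candidate
that unblocks the most reactions (ties broken lexicographically) — until
flux-variability analysis shows every reaction can carry |flux| >
`activity_tol`, or an error lists the unreachable reactions.

**Gene mapping.** Gene pair coflux is the max of c_final over the genes'
associated reaction pairs (GPR membership, not boolean evaluation); genes
sharing a reaction get 1 via the diagonal convention (knocking out a
reaction trivially zeroes itself). Self-coflux is likewise 1 by convention;
nothing downstream consumes the diagonal except the product matrix, where
it is equally inert.

The implementation is verified against an independent brute-force LP oracle
(scipy linprog, one LP per optimum, ratios spelled out separately) on all
toy topologies, to 1e-6.

## Product-matrix clustering

Missing coexpression entries and negative correlations are set to 0 before
multiplication with coflux — no information, no edge — and the product is
clustered with average linkage on D = 1 − product. The dendrogram cut is
this package's own top-down variant of the dynamic hybrid tree-cut idea,
with the deepSplit ∈ {0..4} parameter mapped to a maximum normalized core
scatter of {0.64, 0.73, 0.82, 0.91, 0.95} and a minimum gap of 3/4 of the
complement, as in the reference hybrid method. Leaves that join the tree
only above an absolute outlier height (0.99 on the [0, 1] dissimilarity
scale) stay unassigned; below it, a branch splits into its two children
only when both would form distinct clusters — at least `minClusterSize`
members, core scatter below the deepSplit ceiling, and a sufficient gap
between the children's heights and the join. Branches that cannot split
stay whole, which is what lets the relaxed preset (deepSplit 3,
minClusterSize 6) merge bridged blocks that the stringent preset
(deepSplit 2, minClusterSize 3) separates. Dendrogram ties resolve by input
order, so clustering is deterministic and label-permutation consistent.

Cluster quality is the mean silhouette score (MSS) of member genes on the
same dissimilarity (scikit-learn, precomputed metric), unassigned genes
excluded; clusters are ranked by MSS. Silhouette is undefined with a single
cluster and the code raises rather than inventing a value.

## Pathway self-enrichment

For a pathway P, every universe gene g is scored by the mean correlation to
P's members (excluding g's self-correlation; missing entries drop out of
the mean), the list is sorted descending (ties: score, then gene id), and a
weighted running sum rises by |score|^w (w = 1, normalized over P's
members) at hits and falls by 1/(N − N_hit) at misses. Only positive
enrichment is meaningful for coexpression, so ES is the maximum of the
running sum, in [0, 1]; the leading edge is the hits at or before the peak.
If every hit weight is zero (a gene with no correlation signal) hit
increments fall back to equal weights.

**Null model.** The screen's NES and FDR are calibrated against
*structure-preserving* random sets: size-matched gene sets drawn from the
universe and pushed through the same rank-then-score pipeline, each with
its own ranked list. The classic preranked null — random hit positions on a
fixed ranked list — is measurably anti-conservative for self-enrichment,
because a random set whose members happen to be mutually correlated gets
both a favorable ranking and a high score, a coupling the fixed-list null
cannot express. The structure-preserving null is the same construction used
by the randomization validation (`randomization_validation` permutes gene
labels universe-wide, preserving the correlation matrix, pathway sizes and
gene multiplicities). NES = ES divided by the mean null ES; FDR is the
pooled positive-side permutation FDR across the screen's pathways,
monotonized as a q-value (a set is rejectable at any threshold below its
NES). A pathway with FDR ≤ 0.05 is called coexpressed.

The gene-centric query (`gene_query`) keeps the classic fixed-list
permutation null: there the ranking comes from the query gene's
correlations, not from the tested set, so no such coupling exists. Query
thresholds default to NES ≥ 2 and FDR ≤ 0.05.

Default permutation count is 1,000; the statistical tests in the suite use
200–500 where the check is about calibration rather than resolution.

## Condition extraction

Per cluster and dataset, the mean within-dataset Pearson correlation over
all within-cluster gene pairs (requiring ≥ 2 member genes present and ≥ 4
conditions; otherwise missing). Means are z-scored across clusters within
each dataset — the ranking deliberately rewards datasets where a cluster is
*uniquely* coexpressed — and each cluster's top k = 30 datasets are
reported. Because a dataset's z-scores are relative, a single extreme
condition can drive a spurious top rank; the report therefore flags
datasets whose mean coexpression drops by more than 50% when any single
condition is left out. The across-clusters-within-dataset direction of the
z-score is the primary definition; the transpose is a one-line variant for
sensitivity analysis.

## Synthetic data: what it emulates, and what it does not

The compendium generator is a latent-factor model on log-scale expression:
gene baselines ~ N(7, 2), noise sd 0.1, and module genes add
loading × f_c (f_c ~ N(0,1) per condition) only in the module's active
datasets, giving the closed-form within-module correlation
loading²/(loading² + noise²) ≈ 0.99 at the default loading 0.9. Planted
modules are disjoint gene sets and their activation datasets are disjoint
across modules — the condition-ranking z-score rewards unique coexpression
by design, so overlapping activations would make recovery undefined rather
than difficult. Missing genes are dropped per dataset, sparing genes of
modules active there so the planted signal remains observable.
Batch-contaminated datasets add a gene-specific offset (|offset| = 5 ×
noise sd, random sign per gene) to the second half of their conditions,
reproducing the two-subset structure the skew screen must detect. The
developmental generator plants flat genes (constant shape, small jitter),
ramp and pulse genes, and a bimodal log2 level mixture whose lower
component is flat-shaped low expression. The tissue generator plants
one-hot tissue-specific genes (CV = √6 for 7 tissues), near-uniform
ubiquitous genes, and a low block, with block sizes chosen so the moderate
quantile cut falls inside the value gap between blocks — the
retained/filtered ground truth is unambiguous by construction rather than a
coin flip at a quantile boundary.

None of the generators simulate single-cell count sparsity, read-level
noise, platform effects, or realistic *C. elegans* expression magnitudes;
passing tests demonstrate that the pipeline recovers the structure it is
designed to detect at calibrated noise levels, not that it would perform
identically on any particular real dataset.

## Problem sizes and determinism

The benchmark configurations used throughout the suite and the demo
pipeline are: 20 datasets × 10–20 conditions × 120 genes with 4 planted
8-gene modules for compendium analyses; 2,000 genes × 25 timepoints for
development; 700 genes × 7 tissues; toy metabolic models of 4–40 reactions.
These sizes make every property measurable (factor-model correlations
converge, the mixture fit is stable, clustering is non-trivial) while the
whole pipeline stays interactive. All randomness flows through explicit
`numpy.random.Generator` instances; the pipeline derives one seed per stage
from the master seed by a stable CRC hash, so stages are individually
reproducible and a rerun with the same master seed reproduces every numeric
output to 1e-9 (LP degeneracy affects solver bases, not optima).

## Known limitations

- The adaptive tree cut is a faithful-in-spirit variant, not a port, of the
  published dynamic hybrid algorithm; it has no PAM-like reassignment
  stage, so genes trimmed as outliers are never re-attached to a nearby
  cluster.
- The coflux computation solves O(n²) LPs per direction and is meant for
  models up to a few hundred reactions as implemented; genome-scale models
  would want warm-started LPs or flux-coupling preprocessing.
- The self-enrichment FDR is calibrated per screen; FDRs from separate
  screens are not jointly corrected.
- `amend_diet` is greedy and returns *a* minimal-ish uptake set, not a
  provably minimum one.
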