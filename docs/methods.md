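# Methods

This note documents the models, estimators and design choices behind
`stemprime`, and what the synthetic validation does and does not show
about real data.

## Preprocessing model

Count data are normalized with median-of-ratios size factors: the
per-gene reference is the geometric mean across samples, restricted to
genes positive in every sample; each sample's factor is the median of
its ratios to the reference. No pseudo-reference fallback is applied —
a matrix in which no gene is positive everywhere is an error, because
silently switching reference definitions changes the factors. After
normalization, values are floored at 1 and genes are kept only when the
maximum over within-group means is at least 10 (strictly "lower than
10" is removed). Microarray-style data instead get quantile
normalization (ties receive the mean of the reference values over their
rank range) and a strict overall-mean filter (7.5 or 5.5 depending on
the platform's intensity scale).

Pipeline order is fixed as normalize → floor → presence-filter → log2.
The log2 step before ANOVA is a variance-stabilization choice: the
per-gene tests run on log2 values while fold changes are ratios of
linear-scale group means. Row z-scores use the population (n)
standard deviation; constant rows become zeros with a warning.

## Differential expression

Fold changes follow the signed-ratio convention with magnitude ≥ 1;
the per-gene test is a classical one-way F (for two groups, identical
to the pooled-variance two-sided t-test). Degenerate inputs are given
explicit limits: identical groups → p = 1; zero residual variance with
unequal means → p = 0. Multiple testing uses Benjamini–Hochberg.
Threshold sets are named (de, overlay, highlight, stage, germ), each a
strict inequality on |FC| and on p or q as appropriate; boundary values
never pass. "Most variable" genes are ranked by smallest ANOVA p with
ties broken by larger |FC| then gene id, which keeps every selection
deterministic. PCA fixes component signs by making the loading of the
lexicographically first gene non-negative.

## Mutual-information network inference

MI is estimated in nats by equal-frequency (rank) binning and the
plug-in estimator with Miller–Madow correction, clipped at zero. The
automatic bin count is `B = clip(floor(sqrt(n/3)), 2, 32)` — about
three expected observations per joint cell. This rule keeps the
estimator within a few hundredths of a nat of the continuous MI for
both weak and strong dependence (an `n^(1/3)` rule, by contrast,
under-bins strong dependence and loses ~0.1 nats at ρ = 0.9); the bin
count is configurable per call.

Permutation significance uses the raw (uncorrected, unclipped) plug-in
MI as its test statistic: the bias correction depends only weakly on
the permutation and the zero clip would pile null p-values at 1.
`mi_permutation_p` is the per-pair empirical estimate
`(1 + #{null ≥ obs}) / (n_perm + 1)`. The network builder instead
draws one **pooled** null — valid because, with rank binning of
continuous profiles, every gene carries the same label multiset, so the
permutation null is common to all pairs — and extrapolates below the
empirical floor with an exponential peaks-over-threshold tail fitted to
the top 5 % of the null. Without the extrapolation, a p-cutoff of
1e−6 could never be reached at a tractable permutation count.

An edge enters the network iff the corrected MI is ≥ 0.4 nats and the
pooled-null p is below the cutoff (default 1e−6). DPI pruning then
removes, in every triangle, the edge whose weight is below
`(1 − ε)·min` of the other two (ε = 0.1, the ARACNE-style
multiplicative tolerance; an absolute-difference variant is available
via `absolute=True`). All marks are evaluated on the input graph and
removed simultaneously, which makes the operation order-independent and
idempotent.

The degree diagnostic reports mean degree 2E/N over non-isolated nodes
and an ordinary least-squares fit of log10(node count) on log10(degree)
over observed degrees, giving the scale-free exponent γ and R². Note a
property of rounded inputs: when an exact power law is rounded to
integer counts, degrees whose exact count is below 1 but above 0.5
round up to 1 and flatten the fitted slope; validation constructions
therefore use degrees whose exact count is at least 1.

Markov clustering runs on the column-stochastic matrix with self-loops
at each node's maximum incident weight, alternating expansion (matrix
square), inflation (element-wise power 2.0, column renormalization) and
pruning at 1e−5, until the maximum element change falls below 1e−8.
Clusters are the connected components of the converged support, labeled
1..k by decreasing size then lexicographic smallest member, so the
partition is invariant under node relabeling.

## Developmental-stage overlay

Stage markers come from testing every later stage against the first
(mES) stage: upregulated genes passing |FC| > 2 and q < 0.05 are ranked
by ascending q (ties by larger |FC| then id) and the top N become that
stage's markers. mES markers are the N genes most consistently
downregulated — passing the down thresholds at some later stage and
ranked by their *minimum* downregulation across all later stages. A
gene qualifying for several stages is resolved to the stage of its
maximal stage-mean, so the final catalog is disjoint.

Stage assignment formalizes what is usually done visually on
force-directed layouts: markers keep their catalog stage; a non-marker
gene takes the majority stage among the markers in its MCL cluster
(evidence = supporting marker count), falling back to its direct
neighbors' marker stages when its cluster holds none; ties leave the
gene unassigned rather than guessing. The overlay then counts
differential genes per assigned stage and exports the late-stage list
(stages after mES) for enrichment. Heatmap ordering sorts genes by the
stage of their maximal stage-mean, earliest first, ties by id.

## Enrichment

Enrichment is the hypergeometric upper tail P[X ≥ k] for a query of
size n against a universe of size N with K annotated genes, BH-adjusted
across tested terms. The universe is deliberately the *expressed*
(post-filter) background, not the genome — testing against unexpressed
genes inflates every term. Terms with no query hit are omitted.
Enrichment maps connect significant terms when the combined coefficient
`0.5·|A∩B|/|A∪B| + 0.5·|A∩B|/min(|A|,|B|)` reaches 0.375. The ontology
is a flat child→parent table used only to restrict germ-layer results
to descendants of a configured root term ("development"); ranking of
the top 25 reported terms is by q.

## miRNA classification

Eight tissues merge into four substantive categories (ES = ESC; gonads
= ovary + testis; brain; other somatic = newborn + E9.5 + E12.5). A
miRNA is assigned the unique category holding strictly more than half
of its reads; everything else is "unspecified". E7.5 belongs to no
substantive category, so E7.5-dominated profiles fall to "unspecified"
— a deliberate reading of the category definitions, flagged here
because it pushes borderline embryonic profiles out of the substantive
classes. Genotype composition splits miRNAs by the sign of the fold
change alone (no significance filter), drops "unspecified" calls and
reports per-category counts and fractions per side.

## Synthetic data: what it emulates and what it does not

**Regulatory compendium.** A layered linear-Gaussian cascade: root
genes are unit-variance sources; each non-root gene receives one
*primary* parent (weight ~ U(0.9, 1.1)) and, from any remaining edge
budget, *secondary* parents with weights U(0.3, 0.6), plus Gaussian
noise (sd 0.4). Parents enter standardized, so an edge's
signal-to-noise ratio is the same at every cascade depth — without
this, accumulated variance drives all deep correlations toward 1 and
direct and indirect edges become indistinguishable to DPI. Defaults
(50 genes, 60 edges, 200 samples) put direct-edge dependence safely
above the 0.4-nat cutoff while secondary inputs sit below it; recall
against the planted skeleton is therefore bounded near the primary-edge
fraction, which the validation bands reflect.

**Two-genotype counts.** Negative binomial with variance μ + αμ²
(α = 0.1), log-uniform baselines in (20, 2000), three replicates per
genotype by default (a typical knockout design), planted signed fold
changes applied multiplicatively, optional per-sample library factors.

**Differentiation course.** Eight stages, four replicates each
(≈ the 31-sample scale of real neuronal time courses). On the log2
scale each gene has baseline U(5, 9) plus N(0, 0.5²) noise; stage-s
markers gain 4 log2 units at their stage, and mES markers start 4 up
and decline linearly — monotone in expectation, matching stemness
genes that fade along differentiation.

**Tissue reference.** Specific miRNAs put U(0.55, 0.95) of their reads
into their category's tissues (Dirichlet-split) and the remainder
elsewhere; "unspecified" profiles are near-uniform Dirichlet draws
rejected until no merged category exceeds 0.5.

What passing these tests shows: the estimators, pruning rules,
threshold logic and overlay machinery are implemented correctly and
recover planted structure under the stated noise models. What they do
not show: robustness to batch effects, platform-specific intensity
distributions, correlated biological replicates, mixed direct/indirect
regulation with feedback, or annotation errors — none of which the
generators emulate. Real-compendium performance of MI inference in
particular depends on saturation and nonlinearity the linear-Gaussian
model does not produce.

## Numerical choices and limitations

- All threshold comparisons are strict; every tie-break is documented
  and deterministic (gene id as the final key).
- MI summation uses sorted accumulation so that estimates are
  bit-identical under argument swap.
- The MI significance default is 1e−6; pipelines of this family quote
  cutoffs between 1e−6 and 1e−7, and both are reachable through the
  tail-extrapolated pooled null (`mi_p` in the configuration).
- Mean degree excludes isolated nodes; with isolated nodes present,
  2E/N over all nodes would understate connectivity.
- MCL non-convergence within `max_iter` returns the current partition
  with `converged=False` and a warning rather than raising.
- Batch correction is out of scope: the generators are single-batch,
  and no correction step is provided.
- Problem sizes in the test and validation harnesses (e.g. 50-gene
  cascades, 1200-gene courses, 2000-gene count experiments) are chosen
  to make planted-structure recovery statistically decisive while the
  whole suite stays fast; all scale linearly upward through the same
  API.
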