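# stemprime

Network-level analysis of **differentiation priming** in embryonic stem
cell transcriptomes.

A recurring question in stem-cell biology is whether perturbing a single
regulator (for example knocking out an RNA-binding protein in murine
embryonic stem cells) breaks stemness itself, or leaves the core
pluripotency network intact while *de-repressing* differentiation
programs — priming the cells for lineage entry. Answering it requires
several analyses stitched together: differential expression between
genotypes, a reference gene network inferred from expression compendia,
an overlay of the differential genes onto developmental-stage
territories of that network, enrichment analysis of the affected
processes, and a parallel view of the miRNA pool. `stemprime`
implements that whole pipeline as composable, tested library functions,
plus synthetic-data generators with known ground truth so every stage
can be validated end to end.

## What it computes

- **Preprocessing** (`stemprime.prep`): median-of-ratios size factors
  (the reference for gene *i* is its geometric mean over samples;
  sample *j*'s factor is the median of `count_ij / geomean_i`), flooring
  at 1, the presence filter (keep gene iff max over within-group means
  ≥ 10), quantile normalization, and log2/z transforms.
- **Differential expression** (`stemprime.diffexp`): signed fold change
  (`fc(a,b) = b/a if b ≥ a else −a/b`, so −2 means halved), one-way
  ANOVA on log2 values, Benjamini–Hochberg adjustment, and named
  strict-threshold call sets (e.g. |FC| > 1.5 & p < 0.05), plus PCA,
  hierarchical clustering and volcano tables.
- **Network inference** (`stemprime.netinfer`): pairwise mutual
  information I(X;Y) in nats on equal-frequency bins with Miller–Madow
  correction; permutation significance; an MI-cutoff network; ARACNE-style
  **data-processing-inequality** pruning — in every triangle, edge
  (i,j) is dropped iff `w(i,j) < (1−ε)·min(w(i,k), w(j,k))` with
  ε = 0.1; Pearson co-regulation networks; Markov clustering (MCL,
  inflation 2.0); and a log–log degree regression reporting the
  scale-free exponent γ and R².
- **Developmental overlay** (`stemprime.overlay`): stage-marker
  selection from a differentiation time course (top-N most upregulated
  vs the mES stage at |FC| > 2, q < 0.05; most consistently
  downregulated genes as mES markers), stage assignment of network
  genes by cluster-majority voting, per-stage counts of differential
  genes and peak-stage heatmap ordering.
- **Enrichment** (`stemprime.enrich`): hypergeometric upper-tail GO
  enrichment against the expressed background with BH adjustment,
  enrichment maps linking terms by the combined overlap coefficient,
  and the germ-layer priming intersection (genes upregulated during
  germ-layer differentiation ∩ knockout-responsive genes).
- **miRNA analysis** (`stemprime.mirna`): presence filtering and DE,
  abundance/ratio tables, and tissue-category classification — eight
  mouse tissues merged into ES / gonads / brain / other somatic, a
  miRNA assigned to the category holding > 50 % of its reads, otherwise
  "unspecified".
- **Synthetic data** (`stemprime.synth`): four generators with planted
  ground truth — a linear-Gaussian regulatory cascade compendium, a
  negative-binomial two-genotype count experiment, an 8-stage
  differentiation course with stage markers, and a tissue read-fraction
  reference.

## Worked example

```bash
python examples/02_network_inference.py
```

```
MI edges before/after DPI: 94 / 44
mean degree              : 1.96
precision vs planted     : 0.89
recall vs planted        : 0.65
```

A 50-gene regulatory cascade is simulated over 200 arrays; the
all-versus-all MI network (cutoff 0.4 nats, permutation p < 1e−6) picks
up both direct edges and indirect grandparent/sibling correlations, and
DPI pruning removes roughly half of the raw edges — almost exclusively
the indirect ones, giving 89 % precision at 65 % recall against the
planted skeleton. Secondary (weak-weight) regulatory inputs fall below
the MI cutoff by construction, which is what bounds the recall.

The other examples (`examples/01…05`) cover differential expression,
the stage overlay, enrichment maps and miRNA categories in the same
style, each printing the numbers it computes and what they mean.

A thin command-line interface mirrors the library:

```bash
stemprime simulate twogroup --out-dir sim --seed 1
stemprime prep --counts sim/counts.tsv --groups sim/groups.tsv --out-dir prep
stemprime de --matrix prep/normalized_filtered.tsv --groups sim/groups.tsv --out-dir de
stemprime net mi --matrix compendium.tsv --groups compendium_groups.tsv --out-dir net
```

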