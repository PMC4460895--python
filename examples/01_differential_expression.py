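"""Two-genotype differential expression on simulated knockout counts.

Generates a negative-binomial count experiment with 120 planted
fold-changed genes, runs normalization, flooring, presence filtering and
per-gene ANOVA, and compares the calls against the planted truth.
"""

import stemprime as sp
from stemprime.synth import TwoGroupSpec

mat, truth = sp.simulate_two_group_counts(
    TwoGroupSpec(n_genes=2000, n_per_group=10, n_de=120, fc_values=(4.0, -4.0), seed=1)
)
filtered, removed = sp.preprocess_counts(mat)
table = sp.differential_expression(filtered)
up, down = sp.call_differential(table, "de")

called = set(up) | set(down)
planted = set(truth["gene_id"])
print(f"present after filtering : {len(filtered.gene_ids)} of {len(mat.gene_ids)}")
print(f"DE calls (|FC|>1.5, p<0.05): {len(up)} up / {len(down)} down")
print(f"sensitivity vs planted  : {len(called & planted) / len(planted):.2f}")
print(f"false discovery rate    : {len(called - planted) / max(len(called), 1):.2f}")
# sensitivity near 1 and FDR near 0 mean the ANOVA calls recover the
# planted 4-fold changes almost perfectly at 10 replicates per genotype
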