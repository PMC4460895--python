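"""Hypergeometric GO enrichment and an enrichment map.

Builds a toy universe with two annotated processes, enriches an
upregulated query, and links significant terms by member overlap."""

import pandas as pd

import stemprime as sp
from stemprime.io import GeneSetCollection

universe = [f"g{i:03d}" for i in range(200)]
neuro = frozenset(universe[:15])
cardio = frozenset(universe[10:30])
sets = GeneSetCollection({
    "neuron differentiation": ("GO-like process", neuro),
    "heart development": ("GO-like process", cardio),
})
query = universe[:12]  # upregulated genes concentrated in the neural set

res = sp.hypergeom_enrichment(query, universe, sets)
print(res[["term", "k", "K", "n", "N", "p", "q"]].to_string(index=False))
emap = sp.build_enrichment_map(res, pd.DataFrame(), sets, universe, q_cutoff=0.05)
print(f"map: {emap.n_nodes} significant terms, {emap.n_edges} overlap edges")
# the neural term's tiny q reflects 12/12 query hits out of K=15
# annotated genes; the overlap edge appears when terms share members
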