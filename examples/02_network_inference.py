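"""Mutual-information network inference with DPI pruning.

Simulates a 50-gene regulatory cascade observed over 200 arrays, infers
an all-versus-all MI network (cutoff 0.4 nats, permutation p < 1e-6),
discards likely-indirect edges with the data-processing inequality, and
scores the result against the planted skeleton.
"""

import stemprime as sp
from stemprime.synth import RegulatoryNetworkSpec

mat, skeleton = sp.simulate_regulatory_expression(RegulatoryNetworkSpec(seed=0))
net = sp.build_mi_network(mat, mi_cutoff=0.4, p_cutoff=1e-6, seed=0)
pruned = sp.prune_dpi(net, tolerance=0.1)

truth, found = skeleton.edge_set(), pruned.edge_set()
tp = len(truth & found)
deg, n_edges, mean_degree = sp.degree_stats(pruned)
print(f"MI edges before/after DPI: {net.n_edges} / {pruned.n_edges}")
print(f"mean degree              : {mean_degree:.2f}")
print(f"precision vs planted     : {tp / max(len(found), 1):.2f}")
print(f"recall vs planted        : {tp / len(truth):.2f}")
# DPI removes roughly half the raw MI edges — the indirect
# grandparent/sibling correlations — leaving mostly true direct links
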