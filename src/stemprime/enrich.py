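"""Gene Ontology enrichment statistics and the germ-layer priming workflow.

Enrichment uses the hypergeometric upper tail against the expressed
background (all present post-filter genes), with Benjamini-Hochberg
adjustment across the tested terms.  Enriched terms are connected into
an enrichment map by the combined overlap coefficient.  The germ-layer
workflow intersects genes upregulated during each germ-layer
differentiation with the knockout-responsive genes and reports the most
enriched terms below a configured ontology root ("development").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import anova_p_rows, bh_adjust
from .io import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneNetwork,
    GeneSetCollection,
    StemprimeError,
)
from .prep import mean_presence_filter, quantile_normalize


def hypergeom_enrichment(
    query, universe, term_sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a query gene list.

    Term members are intersected with the universe first; terms with no
    query hit are omitted; p = P[X >= k] for hypergeometric(N, K, n);
    q is BH across all tested (k >= 1) terms.
    """
    query = set(query)
    universe = set(universe)
    outside = query - universe
    if outside:
        raise StemprimeError(f"query gene outside universe: {sorted(outside)[0]!r}")
    N, n = len(universe), len(query)
    rows = []
    for name, (desc, members) in term_sets.sets.items():
        K = len(members & universe)
        k = len(members & query)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, desc, k, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["term", "description", "k", "K", "n", "N", "p"]
    )
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["q", "p", "term"], ignore_index=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def term_similarity(a: frozenset, b: frozenset) -> float:
    """Combined coefficient: mean of Jaccard and overlap coefficients."""
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return 0.5 * inter / len(a | b) + 0.5 * inter / min(len(a), len(b))


def build_enrichment_map(
    up_results: pd.DataFrame,
    down_results: pd.DataFrame,
    term_sets: GeneSetCollection,
    universe,
    q_cutoff: float = 0.05,
    edge_cutoff: float = 0.375,
) -> GeneNetwork:
    """Enrichment map: significant terms as nodes (labeled by query
    direction), edges where the combined member-overlap coefficient
    reaches ``edge_cutoff``."""
    universe = set(universe)
    g = nx.Graph()
    for direction, res in (("up", up_results), ("down", down_results)):
        if res.empty:
            continue
        for _, row in res[res["q"] < q_cutoff].iterrows():
            node = f"{row['term']}|{direction}"
            g.add_node(node, term=row["term"], direction=direction, q=float(row["q"]))
    nodes = list(g.nodes)
    members = {
        node: frozenset(term_sets.members(g.nodes[node]["term"]) & universe)
        for node in nodes
    }
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            sim = term_similarity(members[u], members[v])
            if sim >= edge_cutoff:
                g.add_edge(u, v, weight=sim)
    return GeneNetwork(g, "similarity")


# ---------------------------------------------------------------------------
# ontology (child -> parent table)


def read_ontology(path: str | Path) -> dict[str, set[str]]:
    """Read a child TAB parent edge table into child -> parents."""
    parents: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise StemprimeError(f"ontology line {lineno}: expected 'child<TAB>parent'")
        parents.setdefault(parts[0], set()).add(parts[1])
    return parents


def descendants(root: str, parents: dict[str, set[str]]) -> set[str]:
    """All terms below ``root`` (root included) in a child->parents table."""
    children: dict[str, set[str]] = {}
    known = set(parents)
    for c, ps in parents.items():
        known |= ps
        for p in ps:
            children.setdefault(p, set()).add(c)
    if root not in known:
        raise StemprimeError(f"root term {root!r} absent from the ontology")
    out = {root}
    frontier = [root]
    while frontier:
        t = frontier.pop()
        for c in children.get(t, ()):
            if c not in out:
                out.add(c)
                frontier.append(c)
    return out


# ---------------------------------------------------------------------------
# germ-layer priming


@dataclass
class GermLayerResult:
    layer: str
    n_present: int
    upregulated: list[str]
    intersection: list[str]
    enrichment: pd.DataFrame
    top_terms: pd.DataFrame


def germ_layer_upregulated(
    m: ExpressionMatrix,
    es_group: str,
    presence_threshold: float,
    config: AnalysisConfig,
) -> tuple[list[str], list[str]]:
    """Genes upregulated during one germ-layer differentiation.

    Quantile-normalize, keep genes with overall mean above the
    dataset-specific threshold, one-way ANOVA across ES and the
    differentiated stages, and call genes with FC > germ_fc (maximal
    later-stage mean vs ES mean) and BH q < germ_fdr.  Returns
    (upregulated genes, the present-gene universe).
    """
    norm = quantile_normalize(m)
    present = mean_presence_filter(norm, presence_threshold)
    groups = present.groups
    if es_group not in groups:
        raise StemprimeError(f"ES group {es_group!r} absent from matrix")
    others = [s for s in groups if s != es_group]
    if not others:
        raise StemprimeError("need at least one differentiated stage")
    lin = present.values
    if (lin.to_numpy() <= 0).any():
        raise StemprimeError("values must be positive after presence filtering")
    log2 = np.log2(lin.to_numpy(dtype=float))
    col_idx = {
        s: [lin.columns.get_loc(c) for c in present.samples_of(s)] for s in groups
    }
    p = anova_p_rows([log2[:, col_idx[es_group]]] + [log2[:, col_idx[s]] for s in others])
    q = bh_adjust(p)
    mean_es = lin.iloc[:, col_idx[es_group]].mean(axis=1).to_numpy()
    mean_max = np.max(
        np.column_stack([lin.iloc[:, col_idx[s]].mean(axis=1).to_numpy() for s in others]),
        axis=1,
    )
    up = (mean_max / mean_es > config.germ_fc) & (q < config.germ_fdr)
    return list(lin.index[up]), list(lin.index)


def germ_layer_priming(
    layer_matrices: dict[str, ExpressionMatrix],
    presence_thresholds: dict[str, float],
    trim_de_genes,
    term_sets: GeneSetCollection,
    ontology: dict[str, set[str]],
    root_term: str = "development",
    es_group: str = "ES",
    config: AnalysisConfig | None = None,
) -> dict[str, GermLayerResult]:
    """Per-layer priming analysis.

    For every germ layer: find genes upregulated during its
    differentiation, intersect with the knockout-responsive gene list,
    run enrichment on the intersection against the layer's expressed
    universe, keep terms below ``root_term``, and report the
    ``go_top_terms`` most enriched (ascending q).
    """
    config = config or AnalysisConfig()
    below_root = descendants(root_term, ontology)
    trim_de_genes = set(trim_de_genes)
    out: dict[str, GermLayerResult] = {}
    for layer, m in layer_matrices.items():
        thr = presence_thresholds[layer]
        up, universe = germ_layer_upregulated(m, es_group, thr, config)
        inter = sorted(set(up) & trim_de_genes & set(universe))
        if inter:
            enr = hypergeom_enrichment(inter, universe, term_sets)
            enr = enr[enr["term"].isin(below_root)].reset_index(drop=True)
        else:
            enr = pd.DataFrame(
                columns=["term", "description", "k", "K", "n", "N", "p", "q"]
            )
        top = enr.head(config.go_top_terms).copy()
        out[layer] = GermLayerResult(
            layer=layer,
            n_present=len(universe),
            upregulated=sorted(up),
            intersection=inter,
            enrichment=enr,
            top_terms=top,
        )
    return out
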