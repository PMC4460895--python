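"""Mapping differential-expression results onto reference networks.

Covers the induced subgraph of a curated gene set, fold-change
annotation, stage-marker selection from a differentiation time course,
stage assignment of network genes by cluster-majority voting, per-stage
DE counts, and peak-stage heatmap ordering.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import bh_adjust, _vectorized_two_group_p
from .io import AnalysisConfig, ExpressionMatrix, GeneNetwork, StemprimeError
from .netinfer import ClusterAssignment
from .synth import StageMarkerCatalog


def induced_subgraph(net: GeneNetwork, gene_set) -> tuple[GeneNetwork, float]:
    """Restrict a network to a gene set, keeping only internal edges.

    Returns the subnetwork and the mapped fraction |set ∩ nodes| / |set|.
    """
    gene_set = set(gene_set)
    present = gene_set & set(net.graph.nodes)
    if not present:
        raise StemprimeError("gene set does not intersect the network")
    sub = net.graph.subgraph(present).copy()
    return GeneNetwork(sub, net.weight_kind), len(present) / len(gene_set)


def annotate_fold_changes(
    net: GeneNetwork, de_table: pd.DataFrame, highlight_fc: float = 1.9
) -> GeneNetwork:
    """Attach fold changes to network nodes and flag strong regulation.

    Nodes with |fc| strictly above ``highlight_fc`` get flag ``up`` or
    ``down``; measured nodes below it ``mapped``; the rest ``unmapped``.
    """
    g = net.graph.copy()
    fc_of = de_table["signed_fc"]
    for node in g.nodes:
        if node in fc_of.index:
            fc = float(fc_of.loc[node])
            g.nodes[node]["fold_change"] = fc
            if fc > highlight_fc:
                g.nodes[node]["flag"] = "up"
            elif fc < -highlight_fc:
                g.nodes[node]["flag"] = "down"
            else:
                g.nodes[node]["flag"] = "mapped"
        else:
            g.nodes[node]["flag"] = "unmapped"
    return GeneNetwork(g, net.weight_kind)


def select_stage_markers(
    course: ExpressionMatrix, config: AnalysisConfig | None = None
) -> StageMarkerCatalog:
    """Derive stage-specific marker sets from a differentiation course.

    For every later stage, genes are tested against stage 1 (one-way
    ANOVA on log2 values, |FC| > stage_fc, BH q < stage_fdr); the
    ``stage_top_n`` strongest upregulated genes (ascending q, ties by
    larger |fc| then id) become that stage's markers.  mES (stage 1)
    markers are the ``stage_top_n`` genes most consistently
    downregulated: passing the down thresholds at some later stage,
    ranked by the largest minimum downregulation across all of them.  Genes qualifying for
    several stages are resolved to the stage of their maximal
    stage-mean.
    """
    config = config or AnalysisConfig()
    stages = course.groups
    if len(stages) < 2:
        raise StemprimeError("need at least 2 stages")
    es = stages[0]
    lin = course.values
    if (lin.to_numpy() <= 0).any():
        raise StemprimeError("course matrix must be positive (floor first)")
    log2 = np.log2(lin.to_numpy(dtype=float))
    cols = {s: [lin.columns.get_loc(c) for c in course.samples_of(s)] for s in stages}
    a = log2[:, cols[es]]
    mean_es = lin.iloc[:, cols[es]].mean(axis=1).to_numpy()

    genes = lin.index.to_numpy(dtype=object)
    stage_means = pd.DataFrame(
        {s: lin.iloc[:, cols[s]].mean(axis=1) for s in stages}, index=lin.index
    )

    per_stage_fc = {}
    candidates: dict[str, list[str]] = {}
    down_ok = np.zeros(len(genes), dtype=bool)
    min_down = np.full(len(genes), np.inf)
    for s in stages[1:]:
        b = log2[:, cols[s]]
        p = _vectorized_two_group_p(a, b)
        q = bh_adjust(p)
        mean_s = lin.iloc[:, cols[s]].mean(axis=1).to_numpy()
        fc = np.where(mean_s >= mean_es, mean_s / mean_es, -mean_es / mean_s)
        per_stage_fc[s] = fc

        up = (fc > config.stage_fc) & (q < config.stage_fdr)
        order = np.lexsort((genes, -np.abs(fc), q))
        chosen = [genes[i] for i in order if up[i]][: config.stage_top_n]
        candidates[s] = chosen

        stage_down = (fc < -config.stage_fc) & (q < config.stage_fdr)
        down_ok |= stage_down
        min_down = np.minimum(min_down, -fc)

    # mES markers: differentially down at some later stage, ranked by the
    # weakest (minimum) downregulation across all of them — the most
    # consistently falling genes come first
    order = np.lexsort((genes, -min_down))
    es_markers = [genes[i] for i in order if down_ok[i]][: config.stage_top_n]
    candidates[es] = es_markers

    # resolve genes qualifying for several stages to their peak-mean stage
    stage_index = {s: i for i, s in enumerate(stages)}
    claim: dict[str, list[str]] = {}
    for s, members in candidates.items():
        for gname in members:
            claim.setdefault(gname, []).append(s)
    resolved: dict[str, set[str]] = {s: set() for s in stages}
    for gname, claimants in claim.items():
        if len(claimants) == 1:
            resolved[claimants[0]].add(gname)
        else:
            means = stage_means.loc[gname]
            best = max(claimants, key=lambda s: (means[s], -stage_index[s]))
            resolved[best].add(gname)

    if not claim:
        warnings.warn("no gene passed the stage-marker thresholds", stacklevel=2)
    return StageMarkerCatalog(
        stages=tuple(stages),
        markers={s: frozenset(resolved[s]) for s in stages},
        es_marker_set=frozenset(resolved[es]),
        thresholds={
            "stage_fc": config.stage_fc,
            "stage_fdr": config.stage_fdr,
            "stage_top_n": config.stage_top_n,
        },
    )


@dataclass
class StageAssignment:
    """gene -> (stage label or 'unassigned', supporting marker count)."""

    assignment: dict[str, tuple[str, int]]

    def stage_of(self, gene: str) -> str:
        return self.assignment.get(gene, ("unassigned", 0))[0]

    def assigned(self) -> dict[str, str]:
        return {g: s for g, (s, _) in self.assignment.items() if s != "unassigned"}


def assign_stages(
    net: GeneNetwork, catalog: StageMarkerCatalog, clusters: ClusterAssignment
) -> StageAssignment:
    """Assign every network gene a developmental stage.

    Marker genes keep their catalog stage.  A non-marker gene takes the
    majority stage among the markers sharing its cluster (evidence =
    supporting marker count); if its cluster holds no marker, the
    majority among its direct neighbors' marker stages; unresolvable
    ties or no evidence leave it unassigned.
    """
    marker_stage = catalog.stage_of()
    present_stages = {marker_stage[n] for n in net.graph.nodes if n in marker_stage}
    for s in catalog.stages:
        if catalog.markers.get(s) and s not in present_stages:
            warnings.warn(f"no marker of stage {s!r} present in the network", stacklevel=2)

    by_cluster: dict[int, Counter] = {}
    for node in net.graph.nodes:
        if node in marker_stage and node in clusters.cluster_of:
            by_cluster.setdefault(clusters.cluster_of[node], Counter())[
                marker_stage[node]
            ] += 1

    out: dict[str, tuple[str, int]] = {}
    for node in net.graph.nodes:
        if node in marker_stage:
            out[node] = (marker_stage[node], 1)
            continue
        votes = by_cluster.get(clusters.cluster_of.get(node, -1), Counter())
        if not votes:
            votes = Counter(
                marker_stage[nb] for nb in net.graph.adj[node] if nb in marker_stage
            )
        out[node] = _majority(votes)
    return StageAssignment(out)


def _majority(votes: Counter) -> tuple[str, int]:
    if not votes:
        return ("unassigned", 0)
    best = votes.most_common()
    if len(best) > 1 and best[0][1] == best[1][1]:
        return ("unassigned", 0)
    return (best[0][0], best[0][1])


def overlay_de_counts(
    assignment: StageAssignment,
    up_genes,
    down_genes,
    stages,
) -> tuple[pd.DataFrame, list[str]]:
    """Count DE genes per assigned stage.

    Returns (per-stage up/down count table, the late-stage DE gene list —
    genes assigned any stage after the first — for enrichment).
    """
    stages = list(stages)
    counts = pd.DataFrame(0, index=stages, columns=["up", "down"])
    late: list[str] = []
    for direction, genes in (("up", up_genes), ("down", down_genes)):
        for g in genes:
            s = assignment.stage_of(g)
            if s == "unassigned":
                continue
            counts.loc[s, direction] += 1
            if stages.index(s) >= 1:
                late.append(g)
    counts.index.name = "stage"
    return counts, sorted(set(late))


def order_by_peak_stage(
    course: ExpressionMatrix, genes
) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Order genes by the stage of their maximal stage-mean.

    Earlier peaks come first; ties resolve by gene id.  Returns the
    ordered list, the stage-mean matrix for heatmap rendering, and the
    genes absent from the course (skipped, not fatal).
    """
    stages = course.groups
    present = [g for g in genes if g in course.values.index]
    skipped = [g for g in genes if g not in course.values.index]
    means = pd.DataFrame(
        {s: course.values.loc[present, course.samples_of(s)].mean(axis=1) for s in stages}
    )
    peak = means.to_numpy().argmax(axis=1)
    order = sorted(range(len(present)), key=lambda i: (peak[i], present[i]))
    ordered = [present[i] for i in order]
    return ordered, means.loc[ordered], skipped
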