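"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the study designs the pipeline consumes:

* a multi-array expression compendium driven by a planted sparse
  regulatory cascade (linear Gaussian), for network inference;
* a two-genotype negative-binomial count experiment with planted signed
  fold changes, for differential expression;
* an eight-stage differentiation time course with planted stage-specific
  marker genes, for the developmental overlay;
* per-miRNA read-fraction profiles across eight mouse tissues, for
  tissue-category classification.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import CountMatrix, ExpressionMatrix, GeneNetwork, StemprimeError

DEFAULT_STAGES = (
    "mES",
    "EpiLC",
    "NE",
    "NESC",
    "RG",
    "NB",
    "DS_I_II",
    "DS_IV_V",
)

TISSUES = ("ovary", "testis", "brain", "newborn", "ESC", "E7.5", "E9.5", "E12.5")

#: merged tissue categories; E7.5 belongs to no substantive category, so its
#: reads only ever push a profile towards "unspecified".
CATEGORY_TISSUES = {
    "ES": ("ESC",),
    "gonads": ("ovary", "testis"),
    "brain": ("brain",),
    "other somatic": ("newborn", "E9.5", "E12.5"),
}


# ---------------------------------------------------------------------------
# regulatory compendium


@dataclass
class RegulatoryNetworkSpec:
    """Layered linear-Gaussian cascade behind an expression compendium.

    Root genes are unit-variance Gaussian sources; every downstream gene
    is a weighted sum of its parents plus Gaussian noise of sd
    ``noise_sd``.  Edges connect consecutive layers only, so grandparent
    correlations exist and indirect-edge pruning has work to do.  Each
    non-root gene receives one *primary* parent (weight from
    ``edge_weight_range``, near 1, giving a strong detectable
    dependence); any edge budget beyond that is spent on *secondary*
    parents with smaller weights (``secondary_weight_range``), the way a
    regulatory cascade carries one dominant input per target alongside
    weaker modulating inputs.
    """

    n_genes: int = 50
    n_edges: int = 60
    edge_weight_range: tuple[float, float] = (0.9, 1.1)
    secondary_weight_range: tuple[float, float] = (0.3, 0.6)
    noise_sd: float = 0.4
    n_samples: int = 200
    n_layers: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise StemprimeError("need at least 2 genes")
        if self.n_edges > self.n_genes * (self.n_genes - 1) // 2:
            raise StemprimeError("n_edges exceeds DAG capacity n(n-1)/2")
        if self.noise_sd <= 0:
            raise StemprimeError("noise_sd must be > 0")
        for rng_name in ("edge_weight_range", "secondary_weight_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise StemprimeError(f"{rng_name} must be 0 < lo <= hi")


def simulate_regulatory_expression(
    spec: RegulatoryNetworkSpec,
) -> tuple[ExpressionMatrix, GeneNetwork]:
    """Simulate the compendium; returns (matrix, planted undirected skeleton)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n_layers = spec.n_layers or max(3, int(np.ceil(n / 10)))
    n_layers = min(n_layers, n)
    layer = np.array_split(np.arange(n), n_layers)

    capacity = sum(len(layer[li]) * len(layer[li + 1]) for li in range(n_layers - 1))
    if spec.n_edges > capacity:
        raise StemprimeError(
            f"n_edges={spec.n_edges} exceeds consecutive-layer capacity "
            f"{capacity} at {n_layers} layers"
        )

    lo, hi = spec.edge_weight_range
    slo, shi = spec.secondary_weight_range
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    # primary parents: one dominant input per non-root gene, in order
    layer_of = {int(g): li for li, block in enumerate(layer) for g in block}
    children = [int(j) for li in range(1, n_layers) for j in layer[li]]
    for j in children[: spec.n_edges]:
        i = int(rng.choice(layer[layer_of[j] - 1]))
        edges.append((i, j))
        weights.append(float(rng.uniform(lo, hi)))
    # secondary parents: weaker modulating inputs on the remaining budget
    taken = set(edges)
    candidates = [
        (int(i), int(j))
        for li in range(n_layers - 1)
        for i in layer[li]
        for j in layer[li + 1]
        if (int(i), int(j)) not in taken
    ]
    n_extra = spec.n_edges - len(edges)
    if n_extra > 0:
        pick = rng.choice(len(candidates), size=n_extra, replace=False)
        for k in sorted(pick):
            edges.append(candidates[k])
            weights.append(float(rng.uniform(slo, shi)))

    parents: dict[int, list[tuple[int, float]]] = {}
    for (i, j), w in zip(edges, weights):
        parents.setdefault(j, []).append((i, float(w)))

    # parents enter standardized, so the effective weights keep the
    # signal-to-noise ratio of an edge constant at every cascade depth
    # (otherwise accumulated variance saturates all deep correlations)
    X = np.zeros((n, spec.n_samples))
    for g in range(n):  # index order is a topological order
        if g in parents:
            acc = spec.noise_sd * rng.standard_normal(spec.n_samples)
            for p, w in parents[g]:
                acc = acc + w * (X[p] / X[p].std())
            X[g] = acc
        else:
            X[g] = rng.standard_normal(spec.n_samples)

    genes = [f"g{k:04d}" for k in range(n)]
    samples = [f"array{k:03d}" for k in range(spec.n_samples)]
    values = pd.DataFrame(X, index=genes, columns=samples)
    mat = ExpressionMatrix(values, {s: "compendium" for s in samples}, is_raw=False)
    truth = GeneNetwork.from_edges(
        ((genes[i], genes[j], w) for (i, j), w in zip(edges, weights)),
        weight_kind="truth",
        nodes=genes,
    )
    return mat, truth


# ---------------------------------------------------------------------------
# two-group counts


@dataclass
class TwoGroupSpec:
    """Two-condition negative-binomial count experiment with planted DE.

    Counts follow NB with variance mu + dispersion * mu^2.  DE genes get
    group-2 mean = group-1 mean * fc (or / |fc| for negative fc).  The
    default three replicates per genotype mirror a typical knockout
    RNA-seq design.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    n_de: int = 100
    fc_values: tuple[float, ...] = (2.0, -2.0, 4.0, -4.0)
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    library_size_factors: tuple[float, ...] | None = None
    group_labels: tuple[str, str] = ("fl", "ko")
    gene_ids: tuple[str, ...] | None = None
    de_gene_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise StemprimeError("n_de cannot exceed n_genes")
        if any(abs(f) <= 1 for f in self.fc_values) and self.n_de > 0:
            raise StemprimeError("planted |fc| must be > 1")
        if self.nb_dispersion <= 0:
            raise StemprimeError("dispersion must be > 0")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise StemprimeError("gene_ids length must equal n_genes")
        if self.de_gene_ids is not None and len(self.de_gene_ids) != self.n_de:
            raise StemprimeError("de_gene_ids length must equal n_de")
        if (
            self.library_size_factors is not None
            and len(self.library_size_factors) != 2 * self.n_per_group
        ):
            raise StemprimeError("need one library size factor per sample")


def simulate_two_group_counts(spec: TwoGroupSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate counts; returns (matrix, truth table of planted DE genes)."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_ids) if spec.gene_ids else [f"gene{k:05d}" for k in range(spec.n_genes)]
    lo, hi = spec.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_genes))

    if spec.de_gene_ids is not None:
        idx_of = {g: i for i, g in enumerate(genes)}
        de_idx = np.array([idx_of[g] for g in spec.de_gene_ids], dtype=int)
    else:
        de_idx = rng.choice(spec.n_genes, size=spec.n_de, replace=False)
    fcs = np.array(
        [spec.fc_values[k % len(spec.fc_values)] for k in range(spec.n_de)], dtype=float
    )

    mu = np.repeat(base[:, None], 2, axis=1)  # genes x 2 group means
    for i, fc in zip(de_idx, fcs):
        mu[i, 1] = mu[i, 0] * fc if fc > 0 else mu[i, 0] / abs(fc)

    k = spec.n_per_group
    sf = (
        np.asarray(spec.library_size_factors, dtype=float)
        if spec.library_size_factors is not None
        else np.ones(2 * k)
    )
    alpha = spec.nb_dispersion
    nb_n = 1.0 / alpha
    counts = np.zeros((spec.n_genes, 2 * k), dtype=np.int64)
    for j in range(2 * k):
        m = mu[:, 0] if j < k else mu[:, 1]
        m = m * sf[j]
        p = nb_n / (nb_n + m)
        counts[:, j] = rng.negative_binomial(nb_n, p)

    g1, g2 = spec.group_labels
    samples = [f"{g1}_{i + 1}" for i in range(k)] + [f"{g2}_{i + 1}" for i in range(k)]
    values = pd.DataFrame(counts, index=genes, columns=samples)
    mat = CountMatrix(values, {s: (g1 if i < k else g2) for i, s in enumerate(samples)})
    truth = pd.DataFrame(
        {"gene_id": [genes[i] for i in de_idx], "fc": fcs}
    ).sort_values("gene_id", ignore_index=True)
    return mat, truth


# ---------------------------------------------------------------------------
# differentiation time course


@dataclass
class TimeCourseSpec:
    """Multi-stage differentiation course with planted stage markers.

    Values are linear-scale normalized expression; on the log2 scale each
    gene has baseline mu_g ~ U(5, 9) plus Gaussian noise of sd
    ``background_sd``.  A stage-s marker (s >= 2) gains
    ``marker_amplitude`` log2 units at its own stage; stage-1 (mES)
    markers start ``marker_amplitude`` up and decline linearly to
    baseline at the final stage, so they fall monotonically in
    expectation.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    reps_per_stage: int = 4
    markers_per_stage: int = 50
    n_genes: int = 1200
    marker_amplitude: float = 4.0
    background_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise StemprimeError("need at least 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise StemprimeError("stage labels must be unique")
        if self.markers_per_stage * len(self.stages) > self.n_genes:
            raise StemprimeError("markers_per_stage x stages exceeds n_genes")
        if self.background_sd <= 0:
            raise StemprimeError("background_sd must be > 0")


@dataclass
class StageMarkerCatalog:
    """Ordered stages with disjoint marker gene sets; stage 1 is mES."""

    stages: tuple[str, ...]
    markers: dict[str, frozenset[str]]
    es_marker_set: frozenset[str] = frozenset()
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s, mem in self.markers.items():
            if s not in self.stages:
                raise StemprimeError(f"marker stage {s!r} not in catalog stages")
            if seen & mem:
                raise StemprimeError("marker sets are not disjoint")
            seen |= mem

    def stage_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s, mem in self.markers.items():
            for g in mem:
                out[g] = s
        return out

    @property
    def n_markers(self) -> int:
        return sum(len(m) for m in self.markers.values())


def simulate_stage_course(spec: TimeCourseSpec) -> tuple[ExpressionMatrix, StageMarkerCatalog]:
    """Simulate the course; returns (linear-scale matrix, planted catalog)."""
    rng = np.random.default_rng(spec.seed)
    T = len(spec.stages)
    genes = [f"tc{k:05d}" for k in range(spec.n_genes)]
    mu = rng.uniform(5.0, 9.0, size=spec.n_genes)

    profile = np.zeros((spec.n_genes, T))
    markers: dict[str, frozenset[str]] = {}
    pool = rng.permutation(spec.n_genes)
    pos = 0
    for t, stage in enumerate(spec.stages):
        pick = pool[pos : pos + spec.markers_per_stage]
        pos += spec.markers_per_stage
        markers[stage] = frozenset(genes[i] for i in pick)
        if t == 0:
            # mES markers: amplitude at stage 1, linear decline to 0
            decline = spec.marker_amplitude * (T - 1 - np.arange(T)) / (T - 1)
            profile[pick] += decline
        else:
            profile[pick, t] += spec.marker_amplitude

    cols, labels = [], {}
    log2 = np.zeros((spec.n_genes, T * spec.reps_per_stage))
    j = 0
    for t, stage in enumerate(spec.stages):
        for r in range(spec.reps_per_stage):
            name = f"{stage}_r{r + 1}"
            cols.append(name)
            labels[name] = stage
            log2[:, j] = mu + profile[:, t] + spec.background_sd * rng.standard_normal(
                spec.n_genes
            )
            j += 1

    values = pd.DataFrame(np.exp2(log2), index=genes, columns=cols)
    mat = ExpressionMatrix(values, labels, is_raw=False)
    catalog = StageMarkerCatalog(
        stages=tuple(spec.stages),
        markers=markers,
        es_marker_set=markers[spec.stages[0]],
        thresholds={"planted": True, "amplitude": spec.marker_amplitude},
    )
    return mat, catalog


# ---------------------------------------------------------------------------
# miRNA tissue reference


@dataclass
class TissueReferenceSpec:
    """Read-fraction profiles of miRNAs over 8 mouse tissues.

    ``category_probs`` sets the planted mix over the five categories;
    the default leans heavily on "unspecified", mirroring the large
    ubiquitous fraction seen in tissue atlases.
    """

    n_mirnas: int = 300
    category_probs: dict[str, float] = field(
        default_factory=lambda: {
            "ES": 0.12,
            "gonads": 0.08,
            "brain": 0.08,
            "other somatic": 0.05,
            "unspecified": 0.67,
        }
    )
    specific_fraction_range: tuple[float, float] = (0.55, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_probs.values()) - 1) > 1e-9:
            raise StemprimeError("category_probs must sum to 1")
        lo, hi = self.specific_fraction_range
        if not (0.5 < lo <= hi < 1):
            raise StemprimeError("specific_fraction_range must lie in (0.5, 1)")


def simulate_tissue_reference(spec: TissueReferenceSpec) -> pd.DataFrame:
    """Simulate the reference; rows = miRNAs, columns = 8 tissue fractions
    plus ``planted_category``."""
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.category_probs)
    probs = np.array([spec.category_probs[c] for c in cats])
    t_index = {t: i for i, t in enumerate(TISSUES)}

    rows = []
    planted = []
    for k in range(spec.n_mirnas):
        cat = cats[rng.choice(len(cats), p=probs)]
        frac = np.zeros(len(TISSUES))
        if cat == "unspecified":
            while True:
                frac = rng.dirichlet(np.full(len(TISSUES), 3.0))
                merged = {
                    c: frac[[t_index[t] for t in ts]].sum()
                    for c, ts in CATEGORY_TISSUES.items()
                }
                if max(merged.values()) <= 0.5:
                    break
        else:
            f = rng.uniform(*spec.specific_fraction_range)
            own = CATEGORY_TISSUES[cat]
            within = rng.dirichlet(np.ones(len(own)))
            others = [t for t in TISSUES if t not in own]
            rest = rng.dirichlet(np.ones(len(others)))
            for t, w in zip(own, within):
                frac[t_index[t]] = f * w
            for t, w in zip(others, rest):
                frac[t_index[t]] = (1 - f) * w
        frac = frac / frac.sum()
        rows.append(frac)
        planted.append(cat)

    df = pd.DataFrame(rows, columns=list(TISSUES))
    df.insert(0, "mirna_id", [f"mmu-mir-{k:04d}" for k in range(spec.n_mirnas)])
    df["planted_category"] = planted
    return df
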