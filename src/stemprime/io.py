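"""Core containers and text-format readers/writers.

Matrices travel as TSV (genes in rows, samples in columns), gene sets as
GMT, networks as weighted edge lists, SIF or GraphML, and the run
configuration as a flat ``key: value`` text file.  All identifiers are
opaque, case-sensitive strings; no symbol/accession mapping is attempted.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("stemprime")

NETWORK_FORMATS = ("edge-list-TSV", "SIF", "GraphML")


class StemprimeError(ValueError):
    """Raised for contract violations anywhere in the pipeline."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Genes x samples matrix with a sample->group map.

    ``is_raw`` distinguishes integer read counts from normalized
    (continuous) expression values; the same container serves both.
    """

    values: pd.DataFrame
    group_of: dict[str, str]
    is_raw: bool = True

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise StemprimeError(f"duplicate gene identifier: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise StemprimeError(f"duplicate sample identifier: {dup!r}")
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise StemprimeError(f"samples without group label: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise StemprimeError("matrix values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise StemprimeError("matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def group_means(self) -> pd.DataFrame:
        """Per-gene mean within each group (genes x groups)."""
        out = {}
        for g in self.groups:
            cols = self.samples_of(g)
            if not cols:
                raise StemprimeError(f"group {g!r} has no samples")
            out[g] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)

    def with_values(self, values: pd.DataFrame, is_raw: bool | None = None) -> "CountMatrix":
        keep = {s: self.group_of[s] for s in values.columns}
        return CountMatrix(values, keep, self.is_raw if is_raw is None else is_raw)


#: Normalized continuous matrices use the same container with ``is_raw=False``.
ExpressionMatrix = CountMatrix


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, frozen member set)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise StemprimeError(f"gene set {name!r} is empty")

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph.

    ``weight_kind`` records what the edge weight means: ``"mi"`` (mutual
    information, nats), ``"pearson"`` (correlation), ``"similarity"`` or
    ``"truth"`` (planted skeleton).  Node annotations (fold_change,
    stage_label, marker_flag, in_query_set) live as node attributes on the
    underlying :class:`networkx.Graph`.
    """

    graph: nx.Graph
    weight_kind: str = "mi"

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise StemprimeError("network contains a self-loop")
        for u, v, d in self.graph.edges(data=True):
            w = d.get("weight")
            if w is None or not np.isfinite(w):
                raise StemprimeError(f"edge ({u}, {v}) has no finite weight")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        weight_kind: str = "mi",
        nodes: Iterable[str] | None = None,
    ) -> "GeneNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v, w in edges:
            g.add_edge(u, v, weight=float(w))
        return cls(g, weight_kind)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}


# ---------------------------------------------------------------------------
# configuration

_CONFIG_RANGES = {
    # name: (low, high, low_open, high_open)
    "de_p": (0.0, 1.0, True, True),
    "overlay_p": (0.0, 1.0, True, True),
    "stage_fdr": (0.0, 1.0, True, True),
    "germ_fdr": (0.0, 1.0, True, True),
    "mi_p": (0.0, 1.0, True, True),
    "tissue_fraction": (0.0, 1.0, True, True),
    "de_fc": (1.0, np.inf, False, True),
    "overlay_fc": (1.0, np.inf, False, True),
    "highlight_fc": (1.0, np.inf, False, True),
    "stage_fc": (1.0, np.inf, False, True),
    "germ_fc": (1.0, np.inf, False, True),
}

_INT_FIELDS = {
    "top_variable_genes",
    "top_variable_mirnas",
    "stage_top_n",
    "go_top_terms",
    "n_permutations",
    "random_seed",
}


@dataclass
class AnalysisConfig:
    """Every numeric threshold of the pipeline, with published defaults.

    Fold-change cutoffs are on the signed-ratio scale (|FC| >= 1); all
    threshold comparisons downstream are strict.
    """

    floor_value: float = 1.0
    presence_cutoff: float = 10.0
    top_variable_genes: int = 1000
    top_variable_mirnas: int = 100
    de_fc: float = 1.5
    de_p: float = 0.05
    overlay_fc: float = 1.4
    overlay_p: float = 0.05
    highlight_fc: float = 1.9
    stage_fc: float = 2.0
    stage_fdr: float = 0.05
    stage_top_n: int = 200
    mi_cutoff: float = 0.4
    mi_p: float = 1e-6
    dpi_tolerance: float = 0.1
    pearson_cutoff_es: float = 0.55
    pearson_cutoff_stage: float = 0.90
    germ_fc: float = 3.0
    germ_fdr: float = 0.05
    array_presence_mean_high: float = 7.5
    array_presence_mean_low: float = 5.5
    tissue_fraction: float = 0.5
    go_top_terms: int = 25
    mcl_inflation: float = 2.0
    n_permutations: int = 1000
    random_seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "random_seed":
                continue
            if v <= 0:
                raise StemprimeError(f"{f.name} must be strictly positive, got {v}")
        for name, (lo, hi, lo_open, hi_open) in _CONFIG_RANGES.items():
            v = getattr(self, name)
            ok = (v > lo if lo_open else v >= lo) and (v < hi if hi_open else v <= hi)
            if not ok:
                lob = "(" if lo_open else "["
                hib = ")" if hi_open else "]"
                raise StemprimeError(
                    f"{name}={v} out of range: must be in {lob}{lo}, {hi}{hib}"
                )


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat ``key: value`` file.

    A missing ``path`` yields the defaults.  A partial file overrides only
    the named keys; unknown keys and out-of-range values are hard errors.
    The resolved configuration is logged in full.
    """
    overrides: dict[str, float | int] = {}
    if path is not None:
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise StemprimeError(f"line {lineno}: expected 'key: value', got {line!r}")
            key, _, raw = line.partition(":")
            key = key.strip()
            if key not in known:
                raise StemprimeError(f"line {lineno}: unknown config key {key!r}")
            try:
                val: float | int = int(raw) if key in _INT_FIELDS else float(raw)
            except ValueError as e:
                raise StemprimeError(f"line {lineno}: bad value for {key}: {raw.strip()!r}") from e
            overrides[key] = val
    cfg = AnalysisConfig(**overrides)
    logger.info("resolved configuration: %s", dataclasses.asdict(cfg))
    return cfg


# ---------------------------------------------------------------------------
# matrix IO


def read_count_matrix(
    path: str | Path, groups_path: str | Path, is_raw: bool = True
) -> CountMatrix:
    """Read a genes x samples TSV plus a sample->group TSV.

    The matrix header row holds sample ids; the first column holds gene
    ids.  Errors name the offending gene, sample, or cell (1-based gene
    row and sample column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise StemprimeError(f"duplicate gene identifier: {dup!r}")
    columns = {}
    for j, col in enumerate(df.columns, start=1):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy())) + 1
            raise StemprimeError(
                f"non-numeric value {df[col].iloc[i - 1]!r} at row {i}, column {j}"
            )
        columns[col] = converted
    numeric = pd.DataFrame(columns, index=df.index)
    groups = _read_group_table(groups_path)
    missing = [s for s in numeric.columns if s not in groups]
    if missing:
        raise StemprimeError(f"samples missing from groups file: {missing}")
    return CountMatrix(numeric, {s: groups[s] for s in numeric.columns}, is_raw=is_raw)


def _read_group_table(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise StemprimeError(f"groups file line {lineno}: expected 'sample<TAB>group'")
        if parts[0] in groups:
            raise StemprimeError(f"groups file line {lineno}: duplicate sample {parts[0]!r}")
        groups[parts[0]] = parts[1]
    return groups


def write_count_matrix(m: CountMatrix, path: str | Path, groups_path: str | Path | None = None) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
    if groups_path is not None:
        with open(groups_path, "w", newline="\n") as fh:
            for s in m.sample_ids:
                fh.write(f"{s}\t{m.group_of[s]}\n")


# ---------------------------------------------------------------------------
# gene-set IO (GMT dialect)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise StemprimeError(
                f"GMT line {lineno}: expected at least 3 tab-separated fields"
            )
        name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
        if name in sets:
            raise StemprimeError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = (desc, frozenset(members))
    return GeneSetCollection(sets)


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, (desc, members) in coll.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# network IO


def write_network(net: GeneNetwork, path: str | Path, format: str = "edge-list-TSV") -> None:
    """Write a network as weighted edge-list TSV, SIF, or GraphML.

    Edge-list weights carry 6 decimal digits; SIF uses the interaction
    type ``co``; GraphML keeps node annotations as attributes.
    """
    if format not in NETWORK_FORMATS:
        raise StemprimeError(
            f"unknown network format {format!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )
    if format == "edge-list-TSV":
        with open(path, "w", newline="\n") as fh:
            fh.write(f"#weight_kind\t{net.weight_kind}\n")
            for u, v, d in net.graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['weight']:.6f}\n")
    elif format == "SIF":
        with open(path, "w", newline="\n") as fh:
            for u, v in net.graph.edges:
                fh.write(f"{u}\tco\t{v}\n")
    else:  # GraphML
        g = net.graph.copy()
        g.graph["weight_kind"] = net.weight_kind
        # GraphML cannot carry None attribute values
        for _, d in g.nodes(data=True):
            for k in [k for k, v in d.items() if v is None]:
                del d[k]
        nx.write_graphml(g, path)


def read_network(path: str | Path, format: str = "edge-list-TSV") -> GeneNetwork:
    if format not in NETWORK_FORMATS:
        raise StemprimeError(
            f"unknown network format {format!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )
    if format == "edge-list-TSV":
        kind = "mi"
        g = nx.Graph()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#weight_kind"):
                kind = line.split("\t")[1]
                continue
            u, v, w = line.split("\t")
            g.add_edge(u, v, weight=float(w))
        return GeneNetwork(g, kind)
    if format == "SIF":
        g = nx.Graph()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise StemprimeError(f"malformed SIF line: {line!r}")
            g.add_edge(parts[0], parts[2], weight=1.0)
        return GeneNetwork(g, "unweighted")
    g = nx.read_graphml(path)
    kind = g.graph.get("weight_kind", "mi")
    return GeneNetwork(nx.Graph(g), kind)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
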