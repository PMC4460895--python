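"""Per-gene group statistics: signed fold change, one-way ANOVA,
threshold calls, most-variable selection, PCA, hierarchical clustering.

Fold changes use the signed-ratio convention (fc(a, b) = b/a if b >= a
else -a/b, so |fc| >= 1 and -2 means halved).  ANOVA runs on log2 of
normalized floored values; fold changes are ratios of linear-scale
group means.  All threshold comparisons are strict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import AnalysisConfig, ExpressionMatrix, StemprimeError

#: named threshold sets: (fc_field, sig_field or None, use_q)
THRESHOLD_SETS = {
    "de": ("de_fc", "de_p", False),
    "overlay": ("overlay_fc", "overlay_p", False),
    "highlight": ("highlight_fc", None, False),
    "stage": ("stage_fc", "stage_fdr", True),
    "germ": ("germ_fc", "germ_fdr", True),
}


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Signed ratio of b vs a: b/a if b >= a, else -a/b; fc(x, x) = +1."""
    if mean_a <= 0 or mean_b <= 0:
        raise StemprimeError("fold change needs positive means (flooring violated)")
    return mean_b / mean_a if mean_b >= mean_a else -mean_a / mean_b


def anova_p(groups: list[np.ndarray]) -> float:
    """Classical one-way F-test p-value on (log-scale) group value lists.

    With two groups this equals the two-sided pooled-variance t-test.
    Zero residual variance yields p = 1 for equal means and the p = 0
    limit otherwise.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise StemprimeError("ANOVA needs at least 2 groups")
    if any(len(a) < 1 for a in arrs):
        raise StemprimeError("every group needs at least one observation")
    n = sum(len(a) for a in arrs)
    k = len(arrs)
    if n - k < 1:
        raise StemprimeError("need at least 1 residual degree of freedom")
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ssw == 0:
        return 1.0 if ssb <= 1e-300 else 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(stats.f.sf(f, k - 1, n - k))


def anova_p_rows(groups: list[np.ndarray]) -> np.ndarray:
    """One-way F-test p per row (rows = genes, columns = replicates)."""
    k = len(groups)
    sizes = [g.shape[1] for g in groups]
    n = sum(sizes)
    means = [g.mean(axis=1) for g in groups]
    grand = sum(sz * m for sz, m in zip(sizes, means)) / n
    ssb = sum(sz * (m - grand) ** 2 for sz, m in zip(sizes, means))
    ssw = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means))
    p = np.ones(groups[0].shape[0])
    zero = ssw == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    p[~zero] = stats.f.sf(f[~zero], k - 1, n - k)
    p[zero & (ssb > 1e-300)] = 0.0
    return p


def _vectorized_two_group_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return anova_p_rows([a, b])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def differential_expression(
    m: ExpressionMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene two-group statistics on a linear-scale filtered matrix.

    ``group_a`` is the reference; the fold-change sign reports
    ``group_b`` relative to it.  ANOVA runs on log2 values; fold change
    on linear group means.  Returns a table with columns
    ``mean_<a>, mean_<b>, signed_fc, p, q`` plus a boolean ``call_<set>``
    column per named threshold set.
    """
    config = config or AnalysisConfig()
    groups = m.groups
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise StemprimeError(
                f"matrix has groups {groups}; name group_a and group_b explicitly"
            )
        group_a, group_b = groups
    a_cols, b_cols = m.samples_of(group_a), m.samples_of(group_b)
    if not a_cols or not b_cols:
        raise StemprimeError("both groups need at least one sample")

    lin = m.values
    if (lin.to_numpy() <= 0).any():
        raise StemprimeError("matrix has values <= 0; floor before testing")
    a = np.log2(lin[a_cols].to_numpy(dtype=float))
    b = np.log2(lin[b_cols].to_numpy(dtype=float))
    p = _vectorized_two_group_p(a, b)
    q = bh_adjust(p)

    ma = lin[a_cols].mean(axis=1).to_numpy()
    mb = lin[b_cols].mean(axis=1).to_numpy()
    fc = np.where(mb >= ma, mb / ma, -ma / mb)

    out = pd.DataFrame(
        {
            f"mean_{group_a}": ma,
            f"mean_{group_b}": mb,
            "signed_fc": fc,
            "p": p,
            "q": q,
        },
        index=lin.index,
    )
    out.index.name = "gene_id"
    for name in THRESHOLD_SETS:
        up, down = _call_masks(out, name, config)
        out[f"call_{name}"] = up | down
    return out


def _call_masks(table: pd.DataFrame, set_name: str, config: AnalysisConfig):
    if set_name not in THRESHOLD_SETS:
        raise StemprimeError(
            f"unknown threshold set {set_name!r}; known: {', '.join(THRESHOLD_SETS)}"
        )
    fc_field, sig_field, use_q = THRESHOLD_SETS[set_name]
    fc_cut = getattr(config, fc_field)
    fc = table["signed_fc"].to_numpy()
    up = fc > fc_cut
    down = fc < -fc_cut
    if sig_field is not None:
        sig_cut = getattr(config, sig_field)
        sig = table["q" if use_q else "p"].to_numpy() < sig_cut
        up, down = up & sig, down & sig
    return up, down


def call_differential(
    table: pd.DataFrame, set_name: str, config: AnalysisConfig | None = None
) -> tuple[list[str], list[str]]:
    """Partition a differential table into (up, down) gene lists for a
    named threshold set; all inequalities strict."""
    config = config or AnalysisConfig()
    up, down = _call_masks(table, set_name, config)
    return list(table.index[up]), list(table.index[down])


def top_variable(table: pd.DataFrame, n: int) -> list[str]:
    """The n most variable genes: smallest ANOVA p, ties broken by larger
    |signed_fc|, then lexicographic gene id."""
    if n > len(table):
        warnings.warn(
            f"requested {n} genes but only {len(table)} available; returning all",
            stacklevel=2,
        )
        n = len(table)
    ranked = table.assign(_absfc=table["signed_fc"].abs()).sort_values(
        ["p", "_absfc", "gene_id"] if "gene_id" in table.columns else ["p", "_absfc"],
        ascending=[True, False] + ([True] if "gene_id" in table.columns else []),
        kind="mergesort",
    )
    if "gene_id" not in table.columns:
        # index holds the ids; emulate the id tie-break
        ranked = (
            table.assign(_absfc=table["signed_fc"].abs(), _gid=table.index)
            .sort_values(["p", "_absfc", "_gid"], ascending=[True, False, True], kind="mergesort")
        )
    return list(ranked.index[:n])


def pca_scores(m: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA coordinates on gene-centered log-ready data.

    Returns (scores with one row per sample, variance-explained
    fractions summing to 1).  Component signs are fixed by making the
    loading of the lexicographically first gene non-negative.
    """
    if m.values.shape[1] < 2:
        raise StemprimeError("PCA needs at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    first = int(np.argmin(np.asarray(m.values.index, dtype=object)))
    for c in range(len(s)):
        if u[first, c] < 0:
            u[:, c] = -u[:, c]
            vt[c] = -vt[c]
    scores = (vt.T * s).astype(float)
    total = float((s**2).sum())
    frac = (s**2) / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=m.values.columns, columns=cols), frac


def hierarchical_cluster(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of rows on Euclidean distance.

    Rows are sorted by gene id before linkage so ties resolve by id and
    the leaf order is deterministic.  Returns (scipy linkage matrix,
    leaf order as gene ids).
    """
    if m.values.shape[0] < 2:
        raise StemprimeError("clustering needs at least 2 rows")
    df = m.values.sort_index(kind="mergesort")
    link = hierarchy.linkage(df.to_numpy(dtype=float), method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    return link, [df.index[i] for i in leaves]


def dendrogram_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as a Newick string (branch lengths from
    merge heights)."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def volcano_table(table: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Volcano-plot table: log2 fold change, -log10 p, and the DE call."""
    config = config or AnalysisConfig()
    fc = table["signed_fc"].to_numpy()
    log2fc = np.sign(fc) * np.log2(np.abs(fc))
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(table["p"].to_numpy())
    up, down = _call_masks(table, "de", config)
    call = np.where(up, "up", np.where(down, "down", "ns"))
    return pd.DataFrame(
        {"log2_fc": log2fc, "neg_log10_p": neglogp, "call": call}, index=table.index
    )
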