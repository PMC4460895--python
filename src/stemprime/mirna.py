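"""miRNA-side analysis: presence filtering and differential expression,
abundance/ratio tables, tissue-category classification, and the
genotype-wise category composition.

Tissue classification merges eight mouse tissues into four substantive
categories (ES = ESC; gonads = ovary + testis; brain; other somatic =
newborn + E9.5 + E12.5) and assigns a miRNA to the unique category
holding strictly more than half of its reads; anything else —
including profiles dominated by E7.5, which belongs to no substantive
category — is "unspecified".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diffexp import call_differential, differential_expression
from .io import AnalysisConfig, CountMatrix, StemprimeError
from .prep import preprocess_counts
from .synth import CATEGORY_TISSUES, TISSUES

CATEGORIES = ("ES", "gonads", "brain", "other somatic", "unspecified")


def mirna_de(
    counts: CountMatrix, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, tuple[list[str], list[str]]]:
    """Presence-filter and test miRNAs; returns (table, (up, down)) at
    the standard DE thresholds (|FC| > 1.5, p < 0.05)."""
    config = config or AnalysisConfig()
    filtered, _removed = preprocess_counts(counts, config)
    if filtered.values.empty:
        warnings.warn("no miRNA passed the presence filter", stacklevel=2)
        return pd.DataFrame(), ([], [])
    table = differential_expression(filtered, config=config)
    return table, call_differential(table, "de", config)


def abundance_ratio_table(table: pd.DataFrame, de_genes) -> pd.DataFrame:
    """Abundance/ratio table for DE miRNAs: maximum of the two group
    means against the log2 mean ratio (second group over first)."""
    mean_cols = [c for c in table.columns if c.startswith("mean_")]
    if len(mean_cols) != 2:
        raise StemprimeError("expected exactly two group-mean columns")
    sub = table.loc[[g for g in de_genes if g in table.index]]
    m1 = sub[mean_cols[0]].to_numpy()
    m2 = sub[mean_cols[1]].to_numpy()
    out = pd.DataFrame(
        {
            "max_abundance": np.maximum(m1, m2),
            "log2_ratio": np.log2(m2 / m1),
        },
        index=sub.index,
    )
    out["direction"] = np.where(out["log2_ratio"] >= 0, "up", "down")
    return out


def category_fractions(profile: pd.Series) -> dict[str, float]:
    """Merge an 8-tissue read-fraction profile into category fractions."""
    missing = [t for t in TISSUES if t not in profile.index]
    if missing:
        raise StemprimeError(f"profile missing tissues: {missing}")
    total = float(profile[list(TISSUES)].sum())
    if abs(total - 1.0) > 1e-9:
        raise StemprimeError(f"tissue fractions sum to {total}, expected 1")
    return {
        cat: float(profile[list(ts)].sum()) for cat, ts in CATEGORY_TISSUES.items()
    }


def classify_tissue(profile: pd.Series, threshold: float = 0.5) -> str:
    """Assign the unique merged category holding strictly more than
    ``threshold`` of the reads, else "unspecified"."""
    merged = category_fractions(profile)
    winners = [c for c, f in merged.items() if f > threshold]
    return winners[0] if len(winners) == 1 else "unspecified"


def classify_reference(reference: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Classify every miRNA of a tissue-reference table; index = miRNA id."""
    ref = reference.set_index("mirna_id") if "mirna_id" in reference.columns else reference
    calls = {
        mid: classify_tissue(row, threshold) for mid, row in ref[list(TISSUES)].iterrows()
    }
    return pd.Series(calls, name="category")


def category_composition(
    calls: pd.Series, table: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Category composition of miRNAs higher in each genotype.

    miRNAs are split by the sign of the fold change alone (no
    significance filter); "unspecified" calls are dropped; each side
    reports per-category counts and fractions.  Keys: "higher_in_a"
    (fc < 0, i.e. higher in the reference group) and "higher_in_b".
    """
    common = [m for m in table.index if m in calls.index]
    fc = table.loc[common, "signed_fc"]
    out = {}
    for key, mask in (
        ("higher_in_a", fc < 0),
        ("higher_in_b", fc > 0),
    ):
        side = calls.loc[fc[mask].index]
        side = side[side != "unspecified"]
        counts = side.value_counts()
        df = pd.DataFrame(
            {
                "count": counts,
                "fraction": counts / counts.sum() if len(side) else counts,
            }
        )
        df.index.name = "category"
        out[key] = df
    return out
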