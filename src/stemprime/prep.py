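"""Normalization, flooring, and presence filtering.

Count data go through median-of-ratios size factors, then flooring at 1,
then the presence filter (maximum over group means >= 10).  Array data
are quantile normalized and filtered on the overall mean.  Downstream
statistics run on the log2 of normalized floored values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalysisConfig, CountMatrix, ExpressionMatrix, StemprimeError


@dataclass
class SizeFactorSet:
    """Per-sample positive scaling factors (median-of-ratios)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        arr = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise StemprimeError("size factors must be finite and > 0")


def median_ratio_size_factors(m: CountMatrix) -> SizeFactorSet:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, restricted
    to genes positive in every sample; each sample's factor is the median
    ratio of its counts to the reference.
    """
    arr = m.values.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1)
    if not positive.any():
        raise StemprimeError(
            "no gene has positive counts in every sample; "
            "pseudo-reference fallback is not applied"
        )
    sub = arr[positive]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return SizeFactorSet(pd.Series(factors, index=m.values.columns))


def normalize_counts(m: CountMatrix, factors: SizeFactorSet | None = None) -> ExpressionMatrix:
    """Divide each sample by its size factor; result is no longer raw."""
    if factors is None:
        factors = median_ratio_size_factors(m)
    values = m.values / factors.factors
    return m.with_values(values, is_raw=False)


def floor_values(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Raise every value to at least ``floor``; nothing else changes."""
    return m.with_values(m.values.clip(lower=floor))


def presence_filter(
    m: ExpressionMatrix, cutoff: float = 10.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes whose maximum over within-group means is >= cutoff.

    Returns the filtered matrix and the removed gene ids (order
    preserved in both).
    """
    means = m.group_means()
    keep = means.max(axis=1) >= cutoff
    removed = [g for g, k in keep.items() if not k]
    return m.with_values(m.values.loc[keep]), removed


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the common per-rank mean distribution.

    Ties within a column receive the mean of the reference values over
    their rank range (average-rank convention).
    """
    arr = m.values.to_numpy(dtype=float)
    order = np.sort(arr, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values, is_raw=False)


def mean_presence_filter(m: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Keep genes whose overall mean is strictly greater than threshold."""
    keep = m.values.mean(axis=1) > threshold
    return m.with_values(m.values.loc[keep])


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    if (m.values.to_numpy() <= 0).any():
        raise StemprimeError("log2 of a value <= 0: flooring must precede log transform")
    return m.with_values(np.log2(m.values))


def z_transform_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise z-score with population (n) standard deviation.

    Constant rows become all zeros, with a warning.
    """
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # ddof=0
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant row(s) z-transformed to zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    values = pd.DataFrame((arr - mean) / sd, index=m.values.index, columns=m.values.columns)
    return m.with_values(values)


def preprocess_counts(
    m: CountMatrix, config: AnalysisConfig | None = None
) -> tuple[ExpressionMatrix, list[str]]:
    """The count pipeline: normalize -> floor -> presence filter.

    Returns the linear-scale filtered matrix (log2 is applied by the
    statistics layer) and the removed gene ids.
    """
    config = config or AnalysisConfig()
    norm = normalize_counts(m)
    floored = floor_values(norm, config.floor_value)
    return presence_filter(floored, config.presence_cutoff)
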