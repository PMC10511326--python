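"""Shared numeric conventions used across the package.

A single percentile convention (linear interpolation between order
statistics, the numpy/R type-7 default) is used everywhere percentiles
appear: cover categorisation, wave-power summaries, scenario levers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["quantile", "percentile_of", "zscore", "informative_columns"]


def informative_columns(df):
    """Columns whose between-row variation is numerically meaningful.

    Drops exactly constant columns and columns whose spread is pure float
    jitter relative to their magnitude (e.g. a regional variable repeated
    per reef), which would otherwise produce spurious correlations.
    """
    sd = df.std(ddof=1)
    scale = df.abs().mean().clip(lower=1.0)
    return df.loc[:, (sd > 0) & (sd / scale > 1e-9)]


def quantile(values, q):
    """Quantile with linear interpolation between order statistics (type 7)."""
    return np.quantile(np.asarray(values, dtype=float), q, method="linear")


def percentile_of(value, reference) -> float:
    """Percentile rank of ``value`` within ``reference``.

    Inverse of the type-7 quantile: the sample minimum maps to the 0th
    percentile, the maximum to the 100th, the median of an odd-length
    sample to the 50th; ties resolve to the first matching position.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    if ref.size == 0:
        raise ValueError("reference sample is empty")
    if ref.size == 1:
        return 50.0 if value == ref[0] else (0.0 if value < ref[0] else 100.0)
    # collapse duplicates so np.interp sees strictly increasing knots,
    # keeping the *first* order-statistic position of each tied value
    vals, idx = np.unique(ref, return_index=True)
    ranks = idx / (ref.size - 1)
    return float(np.interp(value, vals, ranks, left=0.0, right=1.0) * 100.0)


def zscore(x, axis=0):
    """Standardize to mean 0, SD 1 (ddof=1); zero-variance columns raise."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance column cannot be standardized")
    return (x - mu) / sd
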