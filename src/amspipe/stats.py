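"""Small shared statistical utilities: multiple-testing corrections and a
two-sample Kolmogorov-Smirnov distance."""

from __future__ import annotations

import numpy as np


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment. NaN entries are ignored (returned as NaN)."""
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    q = np.full(flat.shape, np.nan)
    pv = flat[ok]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        # enforce monotonicity from the largest p down
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.clip(ranked, 0.0, 1.0)
        q[ok] = adj
    return q.reshape(p.shape)


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = int(np.sum(~np.isnan(p)))
    return np.clip(p * m, 0.0, 1.0)


def ks_distance(sample_values, pooled_values) -> float:
    """Two-sample KS statistic sup_x |F_sample(x) - F_pooled(x)|."""
    a = np.asarray(sample_values, dtype=float)
    b = np.asarray(pooled_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_distance requires non-empty vectors")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    grid = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, grid, side="right") / a.size
    cdf_b = np.searchsorted(b_sorted, grid, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))
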