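"""Shared statistical primitives.

Small, dependency-light helpers used across modules: Benjamini-Hochberg
adjustment, vectorised row-wise Pearson correlation with t-based p-values,
the pooled two-sample t statistic, and a two-sample Kolmogorov-Smirnov
wrapper with set-oriented one-sided semantics.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "bh_adjust",
    "pooled_t_test",
    "pearson_rows",
    "ks_compare",
]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are propagated and excluded from the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def pooled_t_test(
    a: np.ndarray, b: np.ndarray, axis: int = -1
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided pooled-variance two-sample t-test along ``axis``.

    Returns ``(t, p)``. Degenerate rows (zero pooled variance) get
    ``t = 0, p = 1`` when the means are equal, else ``t = +/-inf, p = 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    ma = a.mean(axis=axis)
    mb = b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df)
    )
    p = np.where((denom == 0) & (diff == 0), 1.0, p)
    return t, p


def pearson_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r between matching rows of two (n_rows, n_cols)
    matrices, with two-sided p-values from the t transform (n-2 df).

    Rows where either vector is constant yield ``r = p = NaN``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = np.where(denom == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


_KS_ALT = {"two_sided": "two-sided", "less": "greater", "greater": "less"}


def ks_compare(
    values: np.ndarray, other: np.ndarray, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Two-sample KS test with set-oriented one-sided semantics.

    ``alternative='less'`` tests whether ``values`` are stochastically
    *smaller* than ``other`` (their empirical CDF lies above); ``'greater'``
    the reverse.  This deliberately inverts scipy's CDF-oriented naming.
    """
    if alternative not in _KS_ALT:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.ks_2samp(values, other, alternative=_KS_ALT[alternative])
    return float(res.statistic), float(res.pvalue)
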