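"""Shared statistical primitives: Pearson correlation with a t-based p-value,
percentile bootstrap confidence intervals, and Benjamini-Hochberg FDR."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "pearson",
    "columnwise_pearson",
    "bootstrap_ci",
    "bh_fdr",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    ci95: tuple[float, float] | None
    n: int


def pearson(
    x,
    y,
    n_boot: int = 0,
    seed: int | np.random.Generator | None = None,
) -> CorrelationResult:
    """Pearson correlation with the two-sided p from
    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.

    With ``n_boot > 0`` a 95% percentile bootstrap CI (resampling paired
    observations) is attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) >= 1.0:  # degenerate perfect correlation
        p = 0.0
    ci = None
    if n_boot:
        ci = bootstrap_ci(
            lambda xx, yy: sps.pearsonr(xx, yy).statistic,
            (x, y),
            n_boot=n_boot,
            seed=seed,
        )
    return CorrelationResult(r=r, p=p, ci95=ci, n=n)


def columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n, k) matrices.

    Columns with zero variance in either input yield NaN with a warning
    (reported as missing rather than raising, since a single degenerate ROI
    should not abort a whole-cortex analysis).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    bad = denom == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} column(s) with zero variance; r set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=0) / denom
    r[bad] = np.nan
    return r


def _t_based_p(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorised two-sided p for Pearson r at sample size n."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def bootstrap_ci(
    statistic,
    data,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """95% (by default) percentile bootstrap interval for ``statistic``.

    ``data`` is an array or a tuple of equal-length arrays resampled jointly
    along their first axis; ``statistic`` receives the resampled array(s) as
    positional arguments.  A resample on which the statistic fails (raises or
    returns NaN) is redrawn with a warning, up to ``max_redraws`` extra draws
    in total.
    """
    rng = np.random.default_rng(seed)
    arrays = data if isinstance(data, tuple) else (np.asarray(data),)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all data arrays must share their first axis length")
    values = np.empty(n_boot)
    redraws = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            v = float(statistic(*(a[idx] for a in arrays)))
        except Exception:
            v = np.nan
        if np.isnan(v):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    "bootstrap statistic failed on too many resamples"
                )
            warnings.warn("bootstrap resample redrawn (statistic failed)",
                          stacklevel=2)
            continue
        values[i] = v
        i += 1
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(adjusted_p, reject)``; rejection controls the false discovery
    rate at level ``q``.  Adjusted p-values are monotone in the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
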