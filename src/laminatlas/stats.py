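"""Chi-square homogeneity test and two-sample Kolmogorov–Smirnov test.

These two tests carry the pipeline's population-level claims (pattern
frequency differences; size-distribution differences in the granulometry
comparison) and are implemented here from their definitions; only the
reference distributions (chi-square upper tail, Kolmogorov distribution)
come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.stats import chi2 as _chi2_dist

__all__ = ["StatResult", "chi_square", "ks_two_sample"]


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: int | None
    p_value: float
    method: str


def chi_square(table, yates: bool = False) -> StatResult:
    """Pearson chi-square test of independence/homogeneity on a count table.

    ``χ² = Σ (O − E)² / E`` with expectations from the product of the
    marginals over the grand total; ``df = (r − 1)(c − 1)``; p-value from
    the upper tail of the chi-square distribution.  No continuity
    correction by default (``yates=True`` enables it for 2×2 tables).
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any():
        raise ValueError(f"row {int(np.argmax(row == 0))} has zero marginal")
    if (col == 0).any():
        raise ValueError(f"column {int(np.argmax(col == 0))} has zero marginal")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_chi2_dist.sf(stat, df))
    return StatResult(stat, df, p, "pearson-chi-square")


def ks_two_sample(x, y) -> StatResult:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    ``D = sup |ECDF_x − ECDF_y|`` evaluated exactly at the pooled unique
    values (right-continuous ECDFs, which handles ties); the p-value is
    asymptotic, from the Kolmogorov distribution at ``sqrt(nm/(n+m)) D``.
    The asymptotic p is slightly conservative at small sample sizes.
    """
    x = np.sort(np.asarray(x, float).ravel())
    y = np.sort(np.asarray(y, float).ravel())
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.union1d(x, y)
    cdf_x = np.searchsorted(x, pooled, side="right") / n
    cdf_y = np.searchsorted(y, pooled, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    n_eff = n * m / (n + m)
    p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    return StatResult(d, None, min(max(p, 0.0), 1.0), "ks-two-sample-asymptotic")
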