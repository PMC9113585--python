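"""Gradient association tests: Spearman rank correlation and Kruskal-Wallis.

Both tests operate on ranks only.  They relate the first-axis ordination
site scores to site metadata — a rank correlation against the ordinal
depth index, and a rank-based group test across assemblages.  The sign of
a correlation is meaningful only under the package's axis-orientation
convention; its magnitude is orientation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CorrelationResult", "GroupTestResult", "spearman", "kruskal_wallis"]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    H: float
    df: int
    p: float


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation on average ranks, asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p=float(res.pvalue), n=len(x))


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared tail probability."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must be paired")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [values[groups == g] for g in labels]
    H, p = stats.kruskal(*samples)
    return GroupTestResult(H=float(H), df=len(labels) - 1, p=float(p))
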