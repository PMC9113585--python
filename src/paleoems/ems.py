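"""Elements-of-metacommunity-structure metrics and null-model significance.

Three statistics are computed on the ordinated incidence matrix:

* **coherence** — the number of *embedded absences*: zeros lying strictly
  inside a taxon's (column) or site's (row) range between its first and
  last presence along the ordination.  Fewer embedded absences than the
  null expectation means the taxa respond to a common latent gradient
  (positive coherence); more means mutual exclusivity (checkerboards).
* **turnover** — the number of *replacements*: over all unordered taxon
  pairs on the range-completed matrix, the product of the site counts
  unique to each member.  Less turnover than expected means nested ranges.
* **boundary clumping** — Morisita's index of dispersion over the per-site
  tallies of taxon range limits, with a chi-squared dispersion test.
  I > 1: range limits stack at the same sites (clumped); I < 1:
  hyperdispersed.

Significance for coherence and turnover comes from randomised null
matrices (default ``r1``: row sums preserved exactly, columns drawn with
probability proportional to observed column totals), each independently
re-ordinated before its metric is read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .incidence import IncidenceStudy
from .ordination import OrderedMatrix, OrdinationError, _order_values

__all__ = [
    "MetricResult",
    "BoundaryClumpResult",
    "NullDistribution",
    "embedded_absences",
    "range_fill",
    "turnover_replacements",
    "boundary_counts",
    "morisita_boundary_clumping",
    "null_distribution",
    "null_metric_distributions",
    "metric_significance",
    "NULL_MODELS",
]

NULL_MODELS = ("r1", "fixed-fixed", "equiprobable")


@dataclass(frozen=True)
class MetricResult:
    """One EMS metric with its null-model calibration.

    ``direction`` follows the field convention: for coherence, "positive"
    means fewer embedded absences than the simulated mean; for turnover,
    "positive" means more replacements than the simulated mean.
    """

    metric_name: str
    observed: float
    sim_mean: float
    sim_sd: float
    z: float
    p: float
    direction: str
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    def significant_at(self, alpha: float) -> bool:
        return self.p < alpha


@dataclass(frozen=True)
class BoundaryClumpResult:
    morisita_index: float
    p: float
    df: int
    direction: str  # clumped (I>1) | hyperdispersed (I<1) | random
    chi2: float = float("nan")


@dataclass(frozen=True)
class NullDistribution:
    values: np.ndarray
    method: str
    n_sims: int
    seed: int | None
    metric_name: str = ""
    n_redraws: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _as_values(om) -> np.ndarray:
    if isinstance(om, OrderedMatrix):
        return om.values()
    return np.asarray(om, dtype=np.int8)


def embedded_absences(om, axis: str = "both") -> int:
    """Count zeros strictly inside line ranges of the ordered matrix.

    ``axis`` selects which lines are scanned: ``"columns"`` (taxon
    ranges), ``"rows"`` (site ranges) or ``"both"`` (the sum; the
    canonical convention).  Lines with fewer than two presences
    contribute nothing.
    """
    X = _as_values(om)
    total = 0
    if axis in ("columns", "both"):
        total += _line_gaps(X.T)
    if axis in ("rows", "both"):
        total += _line_gaps(X)
    if axis not in ("columns", "rows", "both"):
        raise ValueError(f"unknown axis {axis!r}")
    return int(total)


def _line_gaps(lines: np.ndarray) -> int:
    total = 0
    for line in lines:
        idx = np.flatnonzero(line)
        if len(idx) >= 2:
            total += int(idx[-1] - idx[0] + 1 - len(idx))
    return total


def range_fill(om):
    """Fill each taxon's embedded absences with pseudo-presences.

    Returns the same type as the input (OrderedMatrix or array); the
    original is untouched.  After filling, every column is contiguous.
    """
    X = _as_values(om).copy()
    for j in range(X.shape[1]):
        idx = np.flatnonzero(X[:, j])
        if len(idx) >= 2:
            X[idx[0] : idx[-1] + 1, j] = 1
    if isinstance(om, OrderedMatrix):
        import pandas as pd

        filled = pd.DataFrame(X, index=om.matrix.index, columns=om.matrix.columns)
        return OrderedMatrix(matrix=filled, source_ordination=om.source_ordination)
    return X


def turnover_replacements(om) -> int:
    """Count species replacements between sites on the (range-filled) matrix.

    For each unordered taxon pair (i, j): u_i = number of sites holding i
    but not j, u_j = the converse; the pair contributes u_i * u_j.  This
    equals the count of (site pair, taxon pair) mutual replacements.
    """
    X = _as_values(om).astype(np.int64)
    C = X.T @ X  # joint occurrence counts
    m = X.sum(axis=0)
    U = m[:, None] - C  # u_i for pair (i, j)
    prod = U * U.T
    return int(np.triu(prod, k=1).sum())


def boundary_counts(om) -> np.ndarray:
    """Per-site tallies of taxon range limits.

    Each taxon contributes one boundary at its first-occurrence site and
    one at its last (a single-site taxon contributes both to that site),
    so the tallies sum to twice the number of occupied taxa.
    """
    X = _as_values(om)
    counts = np.zeros(X.shape[0], dtype=np.int64)
    for j in range(X.shape[1]):
        idx = np.flatnonzero(X[:, j])
        if len(idx) == 0:
            continue
        counts[idx[0]] += 1
        counts[idx[-1]] += 1
    return counts


def morisita_boundary_clumping(counts, alpha: float = 0.05) -> BoundaryClumpResult:
    """Morisita's index of dispersion over boundary tallies with chi² test.

    I = q * sum(n_i (n_i - 1)) / (B (B - 1)) with q sites and B total
    boundaries; the dispersion statistic chi² = I (B - 1) + q - B has
    q - 1 degrees of freedom, and the reported p is two-tailed.
    """
    n = np.asarray(counts, dtype=np.int64)
    q = len(n)
    B = int(n.sum())
    if B < 2:
        raise ValueError("need at least 2 boundaries for Morisita's index")
    I = q * float((n * (n - 1)).sum()) / (B * (B - 1))
    chi2 = I * (B - 1) + q - B
    df = q - 1
    upper = stats.chi2.sf(chi2, df)
    lower = stats.chi2.cdf(chi2, df)
    p = min(1.0, 2.0 * min(upper, lower))
    if I > 1:
        direction = "clumped"
    elif I < 1:
        direction = "hyperdispersed"
    else:
        direction = "random"
    return BoundaryClumpResult(morisita_index=I, p=float(p), df=df, direction=direction, chi2=float(chi2))


# ---------------------------------------------------------------------------
# null models


def _r1_matrix(rng: np.random.Generator, row_sums, col_weights) -> np.ndarray:
    """Row sums fixed exactly; columns drawn without replacement with
    probability proportional to observed column totals."""
    m = len(col_weights)
    p = np.asarray(col_weights, dtype=float)
    p = p / p.sum()
    X = np.zeros((len(row_sums), m), dtype=np.int8)
    cols = np.arange(m)
    for i, k in enumerate(row_sums):
        chosen = rng.choice(cols, size=int(k), replace=False, p=p)
        X[i, chosen] = 1
    return X


def _curveball_step(rows: list[set], rng: np.random.Generator) -> None:
    i, j = rng.choice(len(rows), size=2, replace=False)
    a, b = rows[i], rows[j]
    a_only = list(a - b)
    b_only = list(b - a)
    total = a_only + b_only
    k = len(a_only)
    if k == 0 or len(b_only) == 0:
        return
    rng.shuffle(total)
    new_a = set(total[:k])
    new_b = set(total[k:])
    common = a & b
    rows[i] = common | new_a
    rows[j] = common | new_b


def _fixed_fixed_matrix(rng: np.random.Generator, X: np.ndarray) -> np.ndarray:
    """Both margins fixed, via the curveball trade algorithm."""
    rows = [set(np.flatnonzero(r)) for r in X]
    n_trades = 5 * max(len(rows), X.shape[1])
    for _ in range(n_trades):
        _curveball_step(rows, rng)
    out = np.zeros_like(X, dtype=np.int8)
    for i, s in enumerate(rows):
        out[i, list(s)] = 1
    return out


def _equiprobable_matrix(rng: np.random.Generator, shape, fill: int) -> np.ndarray:
    cells = rng.choice(shape[0] * shape[1], size=fill, replace=False)
    X = np.zeros(shape[0] * shape[1], dtype=np.int8)
    X[cells] = 1
    return X.reshape(shape)


def null_matrices(
    X: np.ndarray,
    method: str,
    n_sims: int,
    rng: np.random.Generator,
    reject_degenerate: bool = True,
    max_redraws: int = 100,
):
    """Yield ``n_sims`` random binary matrices under the named null model.

    Degenerate draws (an empty row or column) are rejected and redrawn;
    the generator yields ``(matrix, n_redraws)`` pairs.
    """
    if method not in NULL_MODELS:
        raise ValueError(f"unknown null model {method!r}; supported: {NULL_MODELS}")
    X = np.asarray(X, dtype=np.int8)
    row_sums = X.sum(axis=1)
    col_sums = X.sum(axis=0)
    fill = int(X.sum())
    ff_state = X
    for _ in range(n_sims):
        redraws = 0
        while True:
            if method == "r1":
                sim = _r1_matrix(rng, row_sums, col_sums)
            elif method == "fixed-fixed":
                sim = _fixed_fixed_matrix(rng, ff_state)
            else:
                sim = _equiprobable_matrix(rng, X.shape, fill)
            if not reject_degenerate or (
                (sim.sum(axis=1) > 0).all() and (sim.sum(axis=0) > 0).all()
            ):
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"null model {method!r} produced only degenerate matrices"
                )
        if method == "fixed-fixed":
            ff_state = sim  # Markov chain: continue trading from last state
        yield sim, redraws


def _metric_on_ordered(X_ord: np.ndarray, metric: str, axis: str) -> float:
    if metric == "coherence":
        return float(embedded_absences(X_ord, axis=axis))
    if metric == "turnover":
        return float(turnover_replacements(range_fill(X_ord)))
    raise ValueError(f"unknown metric {metric!r}")


def null_distribution(
    study_or_matrix,
    metric: str,
    method: str = "r1",
    n_sims: int = 1000,
    seed: int | None = None,
    *,
    reordinate: bool = True,
    axis: str = "both",
) -> NullDistribution:
    """Null distribution of one EMS metric over randomised matrices.

    Each simulated matrix is independently re-ordinated (the standard EMS
    convention; set ``reordinate=False`` to score null matrices in their
    drawn order).  Deterministic for a fixed seed.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if metric not in ("coherence", "turnover"):
        raise ValueError(f"unknown metric {metric!r}")
    X = (
        study_or_matrix.values()
        if isinstance(study_or_matrix, IncidenceStudy)
        else np.asarray(study_or_matrix, dtype=np.int8)
    )
    rng = np.random.default_rng(seed)
    values = np.empty(n_sims)
    redraws = 0
    for k, (sim, nr) in enumerate(null_matrices(X, method, n_sims, rng)):
        redraws += nr
        ordered = _ordinate_null(sim) if reordinate else sim
        values[k] = _metric_on_ordered(ordered, metric, axis)
    return NullDistribution(
        values=values,
        method=method,
        n_sims=n_sims,
        seed=seed,
        metric_name=metric,
        n_redraws=redraws,
    )


def _ordinate_null(sim: np.ndarray, max_attempts: int = 25) -> np.ndarray:
    try:
        return _order_values(sim)
    except OrdinationError:
        # rank-1 null draw: score it unordered (metrics still defined)
        return sim


def null_metric_distributions(
    study_or_matrix,
    method: str = "r1",
    n_sims: int = 1000,
    seed: int | None = None,
    *,
    reordinate: bool = True,
    axis: str = "both",
) -> dict[str, NullDistribution]:
    """Coherence and turnover nulls from one shared set of null matrices.

    Each null matrix is ordinated once and both counters are read off it,
    halving the dominant (ordination) cost relative to two independent
    calls to :func:`null_distribution`.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    X = (
        study_or_matrix.values()
        if isinstance(study_or_matrix, IncidenceStudy)
        else np.asarray(study_or_matrix, dtype=np.int8)
    )
    rng = np.random.default_rng(seed)
    coh = np.empty(n_sims)
    turn = np.empty(n_sims)
    redraws = 0
    for k, (sim, nr) in enumerate(null_matrices(X, method, n_sims, rng)):
        redraws += nr
        ordered = _ordinate_null(sim) if reordinate else sim
        coh[k] = embedded_absences(ordered, axis=axis)
        turn[k] = turnover_replacements(range_fill(ordered))
    mk = lambda vals, name: NullDistribution(
        values=vals, method=method, n_sims=n_sims, seed=seed,
        metric_name=name, n_redraws=redraws,
    )
    return {"coherence": mk(coh, "coherence"), "turnover": mk(turn, "turnover")}


def metric_significance(
    observed: float, null: NullDistribution, metric_name: str | None = None
) -> MetricResult:
    """z-test of an observed metric against its null distribution.

    z = (observed - sim_mean) / sim_sd; p = 2 (1 - Phi(|z|)).  A null with
    zero spread yields a flagged degenerate result (p = 1 if the observed
    value equals the mean, else 0).
    """
    name = metric_name or null.metric_name or "metric"
    mean, sd = null.mean, null.sd
    if sd == 0:
        z = 0.0 if observed == mean else float("inf") * np.sign(observed - mean)
        p = 1.0 if observed == mean else 0.0
        degenerate = True
    else:
        z = (observed - mean) / sd
        p = float(2 * stats.norm.sf(abs(z)))
        degenerate = False
    if name == "coherence":
        direction = "positive" if observed < mean else "negative"
    else:  # turnover
        direction = "positive" if observed >= mean else "negative"
    return MetricResult(
        metric_name=name,
        observed=float(observed),
        sim_mean=mean,
        sim_sd=sd,
        z=float(z),
        p=p,
        direction=direction,
        degenerate=degenerate,
    )
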