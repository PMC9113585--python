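"""Subsampling robustness of co-occurrence rates and depth correlations.

Larger groups of sites are repeatedly subsampled down to the size of the
smallest group; each replicate re-runs the filtering and analysis from
scratch, and the replicate distribution supports empirical (add-one,
permutation-style) p-values for between-group comparisons.  Replicates
where the analysis is infeasible (fewer than two analysable taxa, or a
matrix too small/degenerate to ordinate) are recorded as NaN and excluded
from the empirical counts, with the exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cooccur import analyze_pairs, summarize
from .gradients import spearman
from .incidence import IncidenceError, IncidenceStudy, drop_degenerate, drop_singletons
from .ordination import OrdinationError, reciprocal_averaging

__all__ = [
    "SubsampleDistribution",
    "subsample_cooccurrence",
    "subsample_depth_significance",
    "empirical_p",
]


@dataclass(frozen=True)
class SubsampleDistribution:
    """Per-replicate values of one statistic under site subsampling."""

    replicate_values: np.ndarray  # NaN marks infeasible replicates
    n_reps: int
    subsample_size: int
    seed: int | None
    statistic_name: str

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.replicate_values).sum())

    @property
    def valid_values(self) -> np.ndarray:
        v = self.replicate_values
        return v[~np.isnan(v)]


def _subsample(study: IncidenceStudy, labels) -> IncidenceStudy:
    matrix = study.matrix.loc[labels]
    occupied = matrix.sum(axis=0) > 0
    return IncidenceStudy(
        matrix=matrix.loc[:, occupied],
        sites=study.sites.loc[labels],
        provenance=f"{study.provenance}; subsample[{len(labels)} sites]",
    )


def subsample_cooccurrence(
    study: IncidenceStudy,
    size: int,
    n_reps: int,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    expected_threshold: float = 1.0,
) -> SubsampleDistribution:
    """Distribution of the nonrandom co-occurrence percentage under
    subsampling to ``size`` sites (uniform, without replacement)."""
    if size > study.n_sites:
        raise ValueError(f"subsample size {size} exceeds {study.n_sites} sites")
    rng = np.random.default_rng(seed)
    labels = np.asarray(study.site_labels, dtype=object)
    values = np.empty(n_reps)
    for k in range(n_reps):
        chosen = rng.choice(labels, size=size, replace=False)
        sub = drop_singletons(_subsample(study, list(chosen)))
        try:
            if sub.n_taxa < 2:
                raise ValueError("fewer than 2 taxa")
            values[k] = summarize(
                analyze_pairs(sub, alpha=alpha, expected_threshold=expected_threshold)
            ).pct_nonrandom
        except ValueError:
            values[k] = np.nan
    return SubsampleDistribution(
        replicate_values=values,
        n_reps=n_reps,
        subsample_size=size,
        seed=seed,
        statistic_name="pct_nonrandom",
    )


def subsample_depth_significance(
    study: IncidenceStudy,
    size: int,
    n_reps: int,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[int, SubsampleDistribution]:
    """Per-replicate depth correlation: re-ordinate the subsample and test
    site score against depth index.

    Returns ``(n_significant, distribution-of-p-values)`` where
    ``n_significant`` counts replicates with p < alpha.
    """
    if size > study.n_sites:
        raise ValueError(f"subsample size {size} exceeds {study.n_sites} sites")
    rng = np.random.default_rng(seed)
    labels = np.asarray(study.site_labels, dtype=object)
    pvals = np.empty(n_reps)
    for k in range(n_reps):
        chosen = rng.choice(labels, size=size, replace=False)
        sub = _subsample(study, list(chosen))
        try:
            sub = drop_degenerate(sub)
            ordn = reciprocal_averaging(sub)
            depth = sub.sites["depth_index"].to_numpy(dtype=float)
            pvals[k] = spearman(ordn.site_scores.to_numpy(), depth).p
        except (IncidenceError, OrdinationError, ValueError):
            pvals[k] = np.nan
    dist = SubsampleDistribution(
        replicate_values=pvals,
        n_reps=n_reps,
        subsample_size=size,
        seed=seed,
        statistic_name="spearman_p",
    )
    n_sig = int((dist.valid_values < alpha).sum())
    return n_sig, dist


def empirical_p(
    dist: SubsampleDistribution, reference: float, tail: str
) -> float:
    """Add-one empirical tail probability of ``reference`` in the replicate
    distribution: (count at-or-beyond + 1) / (n + 1).

    ``tail="le"`` counts replicates <= reference, ``"ge"`` counts >=.
    NaN-flagged replicates are excluded from both counts.
    """
    values = dist.valid_values
    if len(values) < 1:
        raise ValueError("no valid replicates")
    if tail == "le":
        count = int((values <= reference).sum())
    elif tail == "ge":
        count = int((values >= reference).sum())
    else:
        raise ValueError(f"tail must be 'le' or 'ge', got {tail!r}")
    return (count + 1) / (len(values) + 1)
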