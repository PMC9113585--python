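"""Exact probabilistic pairwise co-occurrence tests.

For two taxa occupying m1 and m2 of N sites, the number of joint sites
under random, independent placement follows the hypergeometric
distribution P(j) = C(m1, j) C(N - m1, m2 - j) / C(N, m2).  A pair is a
positive association when P(co-occurrence >= observed) < alpha, negative
when P(<= observed) < alpha, otherwise random.  Pairs whose expected
co-occurrence falls below a threshold (default 1 site) are excluded: the
discrete test has essentially no power there and such pairs inflate the
denominator of the nonrandom percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .incidence import IncidenceStudy

__all__ = [
    "CooccurrencePair",
    "CooccurrenceSummary",
    "pair_distribution",
    "analyze_pairs",
    "summarize",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class CooccurrencePair:
    """Exact-test record for one unordered taxon pair.

    ``p_lt`` is the probability the two taxa co-occur at a frequency at or
    below the observed count, ``p_gt`` at or above it (the observed count
    is included in both tails, so p_lt + p_gt >= 1).
    """

    taxon1: str
    taxon2: str
    sp1_inc: int
    sp2_inc: int
    n_sites: int
    obs_cooccur: int
    prob_cooccur: float
    exp_cooccur: float
    p_lt: float
    p_gt: float
    classification: str  # positive | negative | random | excluded

    @property
    def confidence(self) -> float:
        """Alternative reporting scale: 1 - min(p_lt, p_gt).

        Some published tables call an association significant when this
        exceeds 0.95; it is reported alongside but is not the decision
        rule here (the tail probabilities are).
        """
        return 1.0 - min(self.p_lt, self.p_gt)


@dataclass(frozen=True)
class CooccurrenceSummary:
    n_pairs_total: int
    n_pairs_analysed: int
    n_positive: int
    n_negative: int

    @property
    def pct_nonrandom(self) -> float:
        return 100.0 * (self.n_positive + self.n_negative) / self.n_pairs_analysed


def pair_distribution(N: int, m1: int, m2: int) -> pd.Series:
    """Exact distribution of the joint count for incidences m1, m2 of N sites.

    Returns a Series indexed by the attainable joint counts
    j in [max(0, m1 + m2 - N), min(m1, m2)]; probabilities sum to 1.
    """
    if m1 > N or m2 > N or m1 < 0 or m2 < 0:
        raise ValueError(f"incidences must lie in [0, N]: N={N}, m1={m1}, m2={m2}")
    lo = max(0, m1 + m2 - N)
    hi = min(m1, m2)
    j = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(j, N, m1, m2)
    return pd.Series(probs, index=j, name="probability")


def _score_pair(
    name1: str,
    name2: str,
    col1: np.ndarray,
    col2: np.ndarray,
    N: int,
    alpha: float,
    expected_threshold: float,
) -> CooccurrencePair:
    m1 = int(col1.sum())
    m2 = int(col2.sum())
    j_obs = int((col1 & col2).sum())
    exp = m1 * m2 / N
    # inclusive tails from the hypergeometric; ties at j_obs in both
    p_lt = float(stats.hypergeom.cdf(j_obs, N, m1, m2))
    p_gt = float(stats.hypergeom.sf(j_obs - 1, N, m1, m2))
    if exp < expected_threshold:
        cls = "excluded"
    elif p_gt < alpha:
        cls = "positive"
    elif p_lt < alpha:
        cls = "negative"
    else:
        cls = "random"
    return CooccurrencePair(
        taxon1=name1,
        taxon2=name2,
        sp1_inc=m1,
        sp2_inc=m2,
        n_sites=N,
        obs_cooccur=j_obs,
        prob_cooccur=m1 * m2 / N**2,
        exp_cooccur=exp,
        p_lt=p_lt,
        p_gt=p_gt,
        classification=cls,
    )


def analyze_pairs(
    study: IncidenceStudy,
    alpha: float = 0.05,
    expected_threshold: float = 1.0,
) -> list[CooccurrencePair]:
    """Score every unordered taxon pair of the study.

    The study should already be singleton-filtered (taxa at a single site
    removed); this is not enforced, but singletons can never reach
    significance and will typically be excluded by the expected-count
    threshold anyway.
    """
    if study.n_taxa < 2:
        raise ValueError("co-occurrence analysis needs at least 2 taxa")
    X = study.values().astype(bool)
    N = study.n_sites
    taxa = study.taxon_labels
    return [
        _score_pair(taxa[i], taxa[j], X[:, i], X[:, j], N, alpha, expected_threshold)
        for i, j in combinations(range(len(taxa)), 2)
    ]


def summarize(pairs: list[CooccurrencePair]) -> CooccurrenceSummary:
    """Tally classifications; excluded pairs leave the denominator."""
    total = len(pairs)
    analysed = sum(1 for p in pairs if p.classification != "excluded")
    if analysed == 0:
        raise ValueError("no analysable pairs (all excluded)")
    return CooccurrenceSummary(
        n_pairs_total=total,
        n_pairs_analysed=analysed,
        n_positive=sum(1 for p in pairs if p.classification == "positive"),
        n_negative=sum(1 for p in pairs if p.classification == "negative"),
    )


def pairs_to_frame(pairs: list[CooccurrencePair]) -> pd.DataFrame:
    """Tabulate pair records in the published supplementary-table schema."""
    frame = pd.DataFrame(
        {
            "sp1": [p.taxon1 for p in pairs],
            "sp2": [p.taxon2 for p in pairs],
            "sp1_inc": [p.sp1_inc for p in pairs],
            "sp2_inc": [p.sp2_inc for p in pairs],
            "obs_cooccur": [p.obs_cooccur for p in pairs],
            "prob_cooccur": [p.prob_cooccur for p in pairs],
            "exp_cooccur": [p.exp_cooccur for p in pairs],
            "p_lt": [p.p_lt for p in pairs],
            "p_gt": [p.p_gt for p in pairs],
            "classification": [p.classification for p in pairs],
            "confidence": [p.confidence for p in pairs],
        }
    )
    # flag pairs where the tail-probability rule and the 0.95-confidence
    # reporting rule would disagree
    conf_sig = frame["confidence"] > 0.95
    tail_sig = frame["classification"].isin(["positive", "negative"])
    frame["rules_disagree"] = conf_sig != tail_sig
    return frame
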