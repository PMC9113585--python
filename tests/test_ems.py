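"""EMS counters against brute-force oracles, and null-model contracts."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paleoems.ems import (
    NullDistribution,
    boundary_counts,
    embedded_absences,
    metric_significance,
    morisita_boundary_clumping,
    null_distribution,
    null_matrices,
    range_fill,
    turnover_replacements,
)


# -- independent oracles ----------------------------------------------------


def embedded_absences_oracle(X, axis="both"):
    """Cell-by-cell scan: a zero is embedded when a 1 exists both before
    and after it along the scanned line."""
    X = np.asarray(X)

    def gaps(lines):
        total = 0
        for line in lines:
            for k in range(len(line)):
                if line[k] == 0 and line[:k].any() and line[k + 1 :].any():
                    total += 1
        return total

    total = 0
    if axis in ("columns", "both"):
        total += gaps(list(X.T))
    if axis in ("rows", "both"):
        total += gaps(list(X))
    return total


def turnover_oracle(X):
    """Exhaustive enumeration over site pairs x taxon pairs of mutual
    replacements (taxon i at one site but not the other, taxon j the
    converse)."""
    X = np.asarray(X).astype(bool)
    n, m = X.shape
    count = 0
    for s1, s2 in combinations(range(n), 2):
        for i, j in combinations(range(m), 2):
            a = X[s1, i] and not X[s2, i]
            b = not X[s1, j] and X[s2, j]
            c = not X[s1, i] and X[s2, i]
            d = X[s1, j] and not X[s2, j]
            if (a and b) or (c and d):
                count += 1
    return count


small_matrices = arrays(
    np.int8,
    st.tuples(st.integers(2, 8), st.integers(2, 8)),
    elements=st.integers(0, 1),
)


class TestEmbeddedAbsences:
    def test_contiguous_matrix_has_none(self):
        X = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]])
        assert embedded_absences(X) == 0

    def test_toy_matches_frozen_oracle_value(self):
        X = np.array([[1, 0, 1, 0], [1, 1, 1, 0], [0, 1, 0, 1], [0, 1, 1, 1]])
        assert embedded_absences(X, axis="columns") == 1
        assert embedded_absences(X, axis="rows") == 2
        assert embedded_absences(X, axis="both") == 3
        assert embedded_absences_oracle(X) == 3

    @settings(max_examples=100, deadline=None)
    @given(values=small_matrices)
    def test_matches_bruteforce_everywhere(self, values):
        for axis in ("columns", "rows", "both"):
            assert embedded_absences(values, axis=axis) == embedded_absences_oracle(
                values, axis=axis
            )


class TestRangeFill:
    def test_single_gap_column(self):
        X = np.array([[1], [0], [1]])
        np.testing.assert_array_equal(range_fill(X), [[1], [1], [1]])

    def test_contiguous_unchanged(self):
        X = np.array([[1, 0], [1, 1], [0, 1]])
        np.testing.assert_array_equal(range_fill(X), X)

    def test_toy_5x4_equals_direct_construction(self):
        X = np.array(
            [[1, 0, 0, 1], [0, 1, 0, 1], [1, 0, 1, 0], [0, 0, 1, 0], [1, 1, 0, 0]]
        )
        expected = np.array(
            [[1, 0, 0, 1], [1, 1, 0, 1], [1, 1, 1, 0], [1, 1, 1, 0], [1, 1, 0, 0]]
        )
        np.testing.assert_array_equal(range_fill(X), expected)
        assert embedded_absences(range_fill(X), axis="columns") == 0

    def test_original_untouched(self):
        X = np.array([[1], [0], [1]], dtype=np.int8)
        range_fill(X)
        assert X[1, 0] == 0


class TestTurnover:
    def test_nested_ranges_have_zero_turnover(self):
        X = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert turnover_replacements(X) == 0

    def test_two_by_two_checkerboard(self):
        assert turnover_replacements(np.array([[1, 0], [0, 1]])) == 1

    def test_filled_toy_frozen_value(self):
        filled = np.array(
            [[1, 0, 0, 1], [1, 1, 0, 1], [1, 1, 1, 0], [1, 1, 1, 0], [1, 1, 0, 0]]
        )
        assert turnover_replacements(filled) == 7

    @settings(max_examples=100, deadline=None)
    @given(
        values=arrays(
            np.int8,
            st.tuples(st.integers(2, 6), st.integers(2, 6)),
            elements=st.integers(0, 1),
        )
    )
    def test_matches_exhaustive_enumeration(self, values):
        assert turnover_replacements(values) == turnover_oracle(values)


class TestBoundaries:
    def test_single_occurrence_contributes_two(self):
        X = np.array([[0], [1], [0]])
        np.testing.assert_array_equal(boundary_counts(X), [0, 2, 0])

    def test_full_span_taxa_stack_at_ends(self):
        X = np.ones((4, 3), dtype=int)
        np.testing.assert_array_equal(boundary_counts(X), [3, 0, 0, 3])

    @settings(max_examples=60, deadline=None)
    @given(values=small_matrices)
    def test_sum_is_twice_occupied_taxa(self, values):
        occupied = (values.sum(axis=0) > 0).sum()
        assert boundary_counts(values).sum() == 2 * occupied

    def test_toy_matches_column_scan(self):
        X = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 1, 0]])
        expected = np.zeros(4, dtype=int)
        for j in range(3):
            rows = np.flatnonzero(X[:, j])
            expected[rows[0]] += 1
            expected[rows[-1]] += 1
        np.testing.assert_array_equal(boundary_counts(X), expected)


class TestMorisita:
    def test_all_boundaries_at_one_site_is_maximal(self):
        counts = [6, 0, 0, 0, 0]
        res = morisita_boundary_clumping(counts)
        assert res.morisita_index == pytest.approx(5.0)  # q sites
        assert res.direction == "clumped"

    def test_spread_boundaries_are_hyperdispersed(self):
        res = morisita_boundary_clumping([1, 1, 1, 1])
        assert res.morisita_index == 0.0
        assert res.direction == "hyperdispersed"

    def test_too_few_boundaries_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            morisita_boundary_clumping([1, 0, 0])

    def test_p_in_unit_interval(self):
        res = morisita_boundary_clumping([4, 2, 0, 3, 1])
        assert 0 <= res.p <= 1
        assert res.df == 4


class TestNullModels:
    def test_r1_preserves_row_sums_every_draw(self):
        rng = np.random.default_rng(0)
        X = (np.random.default_rng(5).random((8, 10)) < 0.4).astype(np.int8)
        X[X.sum(axis=1) == 0, 0] = 1
        for sim, _ in null_matrices(X, "r1", 200, rng):
            np.testing.assert_array_equal(sim.sum(axis=1), X.sum(axis=1))

    def test_r1_column_expectation_tracks_column_sums(self):
        # sparse rows (2-3 of 8 columns) so weighted sampling without
        # replacement stays close to proportional inclusion
        rng = np.random.default_rng(1)
        X = np.zeros((12, 8), dtype=np.int8)
        draw = np.random.default_rng(9)
        weights = np.array([4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 1.0])
        for i in range(12):
            k = 2 + i % 2
            X[i, draw.choice(8, k, replace=False, p=weights / weights.sum())] = 1
        acc = np.zeros(8)
        n = 800
        for sim, _ in null_matrices(X, "r1", n, rng, reject_degenerate=False):
            acc += sim.sum(axis=0)
        mean_cols = acc / n
        obs_cols = X.sum(axis=0)
        assert mean_cols.sum() == pytest.approx(obs_cols.sum())
        corr = np.corrcoef(mean_cols, obs_cols)[0, 1]
        assert corr > 0.95

    def test_fixed_fixed_preserves_both_margins(self):
        rng = np.random.default_rng(2)
        X = (np.random.default_rng(6).random((9, 9)) < 0.4).astype(np.int8)
        X[X.sum(axis=1) == 0, 0] = 1
        X[0, X.sum(axis=0) == 0] = 1
        for sim, _ in null_matrices(X, "fixed-fixed", 50, rng, reject_degenerate=False):
            np.testing.assert_array_equal(sim.sum(axis=1), X.sum(axis=1))
            np.testing.assert_array_equal(sim.sum(axis=0), X.sum(axis=0))

    def test_equiprobable_matches_enumeration_on_2x2(self):
        """With fill 2 on a 2x2 grid there are C(4,2)=6 equally likely
        placements; observed frequencies must match the uniform law."""
        rng = np.random.default_rng(3)
        X = np.array([[1, 0], [0, 1]], dtype=np.int8)
        seen = {}
        n = 3000
        for sim, _ in null_matrices(X, "equiprobable", n, rng, reject_degenerate=False):
            seen[sim.tobytes()] = seen.get(sim.tobytes(), 0) + 1
        assert len(seen) == 6
        freqs = np.array(list(seen.values())) / n
        np.testing.assert_allclose(freqs, 1 / 6, atol=0.03)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown null model"):
            list(null_matrices(np.eye(2, dtype=np.int8), "swap", 1, np.random.default_rng(0)))

    def test_degenerate_draws_redrawn(self):
        rng = np.random.default_rng(4)
        X = np.array([[1, 0, 0], [0, 1, 1]], dtype=np.int8)
        for sim, _ in null_matrices(X, "r1", 100, rng):
            assert (sim.sum(axis=0) > 0).all()
            assert (sim.sum(axis=1) > 0).all()


class TestNullDistributionAndSignificance:
    def test_deterministic_under_fixed_seed(self, toy_study):
        a = null_distribution(toy_study, "coherence", n_sims=30, seed=11)
        b = null_distribution(toy_study, "coherence", n_sims=30, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_n_sims_contract(self, toy_study):
        with pytest.raises(ValueError, match="n_sims"):
            null_distribution(toy_study, "coherence", n_sims=1)

    def test_observed_equal_to_mean(self):
        null = NullDistribution(
            values=np.array([4.0, 6.0, 5.0, 5.0]), method="r1", n_sims=4, seed=0,
            metric_name="coherence",
        )
        res = metric_significance(5.0, null)
        assert res.z == 0
        assert res.p == 1

    def test_two_sigma_gives_norm_tail(self):
        values = np.array([0.0, 2.0])  # mean 1, sd sqrt(2)
        null = NullDistribution(values=values, method="r1", n_sims=2, seed=0,
                                metric_name="coherence")
        res = metric_significance(1.0 + 2 * null.sd, null)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_sd_flagged_degenerate(self):
        null = NullDistribution(values=np.array([3.0, 3.0, 3.0]), method="r1",
                                n_sims=3, seed=0, metric_name="turnover")
        res = metric_significance(7.0, null)
        assert res.degenerate
        assert res.p == 0

    def test_coherence_direction_convention(self):
        null = NullDistribution(values=np.array([10.0, 12.0, 14.0]), method="r1",
                                n_sims=3, seed=0, metric_name="coherence")
        assert metric_significance(2.0, null).direction == "positive"
        assert metric_significance(20.0, null).direction == "negative"

    def test_turnover_direction_convention(self):
        null = NullDistribution(values=np.array([10.0, 12.0, 14.0]), method="r1",
                                n_sims=3, seed=0, metric_name="turnover")
        assert metric_significance(20.0, null).direction == "positive"
        assert metric_significance(2.0, null).direction == "negative"
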