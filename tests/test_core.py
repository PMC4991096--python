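"""Unit and property tests for the per-gene ranking statistics."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from signsum.core import (
    DegenerateGeneWarning,
    SubsampleScheme,
    TopKConvergence,
    rank_genes,
    sign_sum,
    subsample_t,
    welch_t,
)
from signsum.data import ExpressionMatrix

from conftest import make_matrix


def one_gene(disease, normal):
    disease, normal = list(disease), list(normal)
    return ExpressionMatrix(
        values=np.array([disease + normal], dtype=float),
        gene_ids=["g"],
        group=[1] * len(disease) + [0] * len(normal),
    )


# ---------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------

class TestWelchT:
    def test_hand_example(self):
        # means 1 and 4, both variances 2, equal groups of 2:
        # T = sqrt(4) * 3 / sqrt(8)
        m = one_gene([3.0, 5.0], [0.0, 2.0])
        assert welch_t(m).scores[0] == pytest.approx(3.0 / np.sqrt(2.0))

    def test_zero_for_identical_groups(self):
        m = one_gene([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert welch_t(m).scores[0] == 0.0

    def test_sign_flips_with_large_negative_shift(self):
        base = one_gene([3.0, 5.0], [0.0, 2.0])
        shifted = one_gene([3.0 - 10.0, 5.0 - 10.0], [0.0, 2.0])
        assert welch_t(base).scores[0] > 0
        assert welch_t(shifted).scores[0] < 0
        # only the numerator changes under a disease-group shift
        assert welch_t(shifted).scores[0] == pytest.approx(
            welch_t(base).scores[0] - 2.0 * 10.0 / np.sqrt(8.0)
        )

    def test_degenerate_gene_flagged_not_infinite(self):
        m = ExpressionMatrix(
            values=np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]]),
            gene_ids=["flat", "ok"],
            group=[1, 1, 0, 0],
        )
        with pytest.warns(DegenerateGeneWarning):
            table = welch_t(m)
        assert np.isnan(table.scores[0])
        assert table.degenerate[0] and not table.degenerate[1]
        assert np.isfinite(table.scores[1])

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError, match="2 samples"):
            welch_t(one_gene([1.0], [0.0, 1.0]))


# ---------------------------------------------------------------------
# sign-sum statistic
# ---------------------------------------------------------------------

class TestSignSum:
    def test_complete_separation(self):
        m = one_gene([5.0, 6.0], [0.0, 0.1])
        table = sign_sum(m, SubsampleScheme(a=1, b=1, mode="exact"))
        assert table.scores[0] == 1.0

    def test_hand_enumeration_with_tie(self):
        # disease (1, 3): subset mean 2 beats all normal 2-subset means
        m = one_gene([1.0, 3.0], [0.0, 1.0, 2.0])
        scheme = SubsampleScheme(a=2, b=2, mode="exact")
        assert sign_sum(m, scheme).scores[0] == 1.0
        # disease (0, 1): mean 0.5; differences (0, -0.5, -1.0) -> H(0)=1
        m2 = one_gene([0.0, 1.0], [0.0, 1.0, 2.0])
        assert sign_sum(m2, scheme).scores[0] == pytest.approx(1.0 / 3.0)

    def test_equals_mann_whitney_proportion_at_a1_b1(self, wide_matrix):
        scheme = SubsampleScheme(a=1, b=1, mode="exact")
        got = sign_sum(wide_matrix, scheme).scores
        d, m = wide_matrix.disease, wide_matrix.normal
        for j in range(wide_matrix.p):
            brute = sum(
                1.0 for x in d[j] for y in m[j] if x >= y
            ) / (d.shape[1] * m.shape[1])
            assert got[j] == pytest.approx(brute)

    def test_exact_is_multiple_of_grid(self, small_matrix):
        scheme = SubsampleScheme(a=2, b=3, mode="exact")
        k = scheme.n_pairs(small_matrix.n1, small_matrix.n0)
        scores = sign_sum(small_matrix, scheme).scores
        assert np.all(scores >= 0.0) and np.all(scores <= 1.0)
        assert np.allclose(np.round(scores * k), scores * k, atol=1e-9)

    def test_label_swap_antisymmetry(self, small_matrix):
        fwd = sign_sum(small_matrix, SubsampleScheme(2, 3, "exact")).scores
        swapped = ExpressionMatrix(
            values=small_matrix.values,
            gene_ids=small_matrix.gene_ids,
            group=1 - small_matrix.group,
        )
        rev = sign_sum(swapped, SubsampleScheme(3, 2, "exact")).scores
        assert np.allclose(fwd, 1.0 - rev, atol=1e-12)

    def test_location_monotonicity(self, small_matrix):
        scheme = SubsampleScheme(2, 2, "exact")
        before = sign_sum(small_matrix, scheme).scores
        shifted = ExpressionMatrix(
            values=small_matrix.values
            + 0.7 * (small_matrix.group == 1)[None, :],
            gene_ids=small_matrix.gene_ids,
            group=small_matrix.group,
        )
        after = sign_sum(shifted, scheme).scores
        assert np.all(after >= before - 1e-12)

    @pytest.mark.parametrize("a,b", [(1, 3), (2, 2)])
    def test_monte_carlo_consistent_with_exact(self, a, b, rng):
        matrix = make_matrix(60, 6, 6, rng, shift=0.5)
        exact = sign_sum(matrix, SubsampleScheme(a, b, "exact")).scores
        mc = sign_sum(
            matrix, SubsampleScheme(a, b, "monte_carlo", n_draws=4000, seed=5)
        )
        stderr = np.maximum(mc.mc_stderr, 1e-12)
        frac_ok = np.mean(np.abs(mc.scores - exact) <= 4.0 * stderr)
        assert frac_ok >= 0.95

    def test_singleton_estimator_unbiased_against_exact(self, rng):
        # a=1 path shares normal subsets across singletons; still targets
        # the enumeration average
        matrix = make_matrix(40, 8, 6, rng, shift=0.5)
        exact = sign_sum(matrix, SubsampleScheme(1, 3, "exact")).scores
        mc = sign_sum(
            matrix, SubsampleScheme(1, 3, "monte_carlo", n_draws=3000, seed=9)
        )
        stderr = np.maximum(mc.mc_stderr, 1e-12)
        assert np.mean(np.abs(mc.scores - exact) <= 4.0 * stderr) >= 0.95

    def test_scheme_validation(self, small_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            sign_sum(small_matrix, SubsampleScheme(a=7, b=1, mode="exact"))
        with pytest.raises(ValueError, match="monte_carlo"):
            sign_sum(
                small_matrix,
                SubsampleScheme(a=3, b=3, mode="exact", exact_ceiling=10),
            )

    def test_convergence_check_stops_and_is_deterministic(self, rng):
        matrix = make_matrix(30, 10, 10, rng, shift=1.0)
        scheme = SubsampleScheme(
            1, 3, "monte_carlo", n_draws=100, seed=3,
            convergence_check=TopKConvergence(k=5, tol=0), max_draws=800,
        )
        first = sign_sum(matrix, scheme).scores
        second = sign_sum(matrix, scheme).scores
        assert np.array_equal(first, second)

    def test_per_gene_streams_independent_of_p(self, rng):
        # the same gene embedded in a bigger matrix gets the same score
        matrix = make_matrix(10, 8, 8, rng, shift=0.5)
        sub = ExpressionMatrix(
            values=matrix.values[:3],
            gene_ids=matrix.gene_ids[:3],
            group=matrix.group,
        )
        scheme = SubsampleScheme(1, 4, "monte_carlo", n_draws=500, seed=11)
        full = sign_sum(matrix, scheme).scores[:3]
        part = sign_sum(sub, scheme).scores
        assert np.array_equal(full, part)


# ---------------------------------------------------------------------
# subsample t
# ---------------------------------------------------------------------

class TestSubsampleT:
    @pytest.mark.parametrize("a,b", [(1, 1), (2, 3), (3, 2)])
    def test_exact_identity_with_welch(self, small_matrix, a, b):
        t = welch_t(small_matrix).scores
        u = subsample_t(small_matrix, SubsampleScheme(a, b, "exact")).scores
        expect = np.sqrt((a + b) / small_matrix.n) * t
        assert np.allclose(u, expect, atol=1e-12)

    def test_exact_matches_literal_enumeration(self, rng):
        # brute-force oracle over all subset pairs on one gene
        matrix = make_matrix(1, 5, 4, rng, shift=0.5)
        a, b = 2, 2
        d, m = matrix.disease[0], matrix.normal[0]
        n = matrix.n
        s = np.sqrt(
            d.var(ddof=1) * n / len(d) + m.var(ddof=1) * n / len(m)
        )
        pairs = [
            np.sqrt(a + b) * (np.mean(ds) - np.mean(ms)) / s
            for ds in combinations(d, a)
            for ms in combinations(m, b)
        ]
        got = subsample_t(matrix, SubsampleScheme(a, b, "exact")).scores[0]
        assert got == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_full_subsets_recover_welch(self, small_matrix):
        scheme = SubsampleScheme(small_matrix.n1, small_matrix.n0, "exact")
        u = subsample_t(small_matrix, scheme).scores
        assert np.allclose(u, welch_t(small_matrix).scores, atol=1e-12)

    def test_monte_carlo_converges_to_exact(self, small_matrix):
        exact = subsample_t(small_matrix, SubsampleScheme(2, 2, "exact")).scores
        mc = subsample_t(
            small_matrix,
            SubsampleScheme(2, 2, "monte_carlo", n_draws=20_000, seed=4),
        )
        assert np.allclose(mc.scores, exact, atol=0.05)
        # rough consistency with the reported Monte-Carlo error
        assert np.mean(np.abs(mc.scores - exact) <= 4 * mc.mc_stderr) >= 0.9


# ---------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------

class TestRankGenes:
    def test_descending_sort(self):
        from signsum.core import ScoreTable

        table = ScoreTable(
            np.array(["gene1", "gene2", "gene3"], dtype=object),
            "sign_sum", np.array([0.9, 0.1, 0.5]),
        )
        ranked = rank_genes(table)
        assert list(ranked["gene_id"]) == ["gene1", "gene3", "gene2"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_tie_break_by_welch_then_id(self):
        # two genes with identical sign-sum scores: full-data |t| decides
        values = np.array([
            [0.0, 0.2, 5.0, 5.2],   # strong, low variance
            [-1.0, 1.2, 4.0, 6.2],  # same means, larger variance -> lower |t|
        ])
        m = ExpressionMatrix(values=values, gene_ids=["b", "a"],
                             group=[0, 0, 1, 1])
        table = sign_sum(m, SubsampleScheme(1, 1, "exact"))
        assert table.scores[0] == table.scores[1] == 1.0
        ranked = rank_genes(table, matrix=m)
        assert list(ranked["gene_id"]) == ["b", "a"]
        # without the matrix the fallback is lexicographic gene_id
        ranked_plain = rank_genes(table)
        assert list(ranked_plain["gene_id"]) == ["a", "b"]

    def test_orientation_reflection_symmetry(self, small_matrix):
        scheme = SubsampleScheme(1, 2, "exact")
        base = rank_genes(
            sign_sum(small_matrix, scheme), "oriented_by_full_t",
            matrix=small_matrix,
        )
        flipped_values = small_matrix.values.copy()
        flipped_values[0] = -flipped_values[0]
        flipped = ExpressionMatrix(
            values=flipped_values, gene_ids=small_matrix.gene_ids,
            group=small_matrix.group,
        )
        after = rank_genes(
            sign_sum(flipped, scheme), "oriented_by_full_t", matrix=flipped
        )
        g = small_matrix.gene_ids[0]
        rank_before = base.loc[base["gene_id"] == g, "rank"].iloc[0]
        rank_after = after.loc[after["gene_id"] == g, "rank"].iloc[0]
        assert rank_before == rank_after

    def test_degenerate_genes_rank_last(self):
        values = np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]])
        m = ExpressionMatrix(values=values, gene_ids=["flat", "ok"],
                             group=[1, 1, 0, 0])
        with pytest.warns(DegenerateGeneWarning):
            ranked = rank_genes(welch_t(m), matrix=m)
        assert list(ranked["gene_id"])[-1] == "flat"


# ---------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.integers(min_value=-5, max_value=5), min_size=8, max_size=8
    ),
    a=st.integers(1, 3),
    b=st.integers(1, 4),
)
def test_sign_sum_bounds_and_grid(data, a, b):
    """U^S always lies in [0, 1] and, exactly, on the 1/(k0 k1) grid —
    including integer-valued data exercising the H(0) = 1 tie rule."""
    m = one_gene(data[:4], data[4:])
    scheme = SubsampleScheme(a=min(a, 4), b=min(b, 4), mode="exact")
    u = sign_sum(m, scheme).scores[0]
    k = scheme.n_pairs(4, 4)
    assert 0.0 <= u <= 1.0
    assert round(u * k) == pytest.approx(u * k, abs=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(shift=st.floats(-3.0, 3.0), seed=st.integers(0, 10_000))
def test_wilcoxon_count_reduction(shift, seed):
    """At a = b = 1, exact U^S * (n0 n1) is the count of pairs with
    disease >= normal."""
    rng = np.random.default_rng(seed)
    m = make_matrix(3, 5, 6, rng, shift=shift)
    u = sign_sum(m, SubsampleScheme(1, 1, "exact")).scores
    for j in range(3):
        count = sum(
            1 for x in m.disease[j] for y in m.normal[j] if x >= y
        )
        assert u[j] * 30 == pytest.approx(count)
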