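"""Hypergeometric tail, BH correction, and overlap analysis."""

import math
from itertools import product

import numpy as np
import pytest

from scattergate import DomainError, GeneSet, GeneSetCollection, bh_fdr, hypergeom_tail_p, overlap_analysis
from scattergate.enrichment import log_hypergeom_tail


def exhaustive_tail(N: int, K: int, n: int, k: int) -> float:
    """Independent oracle: sum the pmf with exact integer binomials."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def bh_definition(p: list[float]) -> list[float]:
    """Step-up BH written directly from the definition: q_(i) = min_{j>=i} m*p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(1.0, running)
    return q


class TestHypergeomTail:
    def test_k_zero_is_one(self):
        assert hypergeom_tail_p(20, 5, 10, 0) == 1.0

    def test_worked_example(self):
        # sum_{j=4..5} C(5,j) C(15,10-j) / C(20,10) = 28028/184756
        assert hypergeom_tail_p(20, 5, 10, 4) == pytest.approx(28028 / 184756, rel=1e-12)

    def test_full_capture_counting_argument(self):
        # only one 5-subset of 20 equals the geneset exactly
        assert hypergeom_tail_p(20, 5, 5, 5) == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_enumeration_oracle_small_sweep(self):
        for N in (5, 12, 18):
            for K, n in product(range(N + 1), repeat=2):
                for k in range(max(0, n + K - N), min(n, K) + 1):
                    assert hypergeom_tail_p(N, K, n, k) == pytest.approx(
                        exhaustive_tail(N, K, n, k), rel=1e-10
                    )

    def test_matches_scipy_cross_check(self):
        from scipy.stats import hypergeom

        for N, K, n, k in [(1000, 50, 100, 12), (5000, 200, 500, 35), (100, 10, 20, 10)]:
            assert hypergeom_tail_p(N, K, n, k) == pytest.approx(
                float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9
            )

    def test_normalization(self):
        """The pmf recovered from tail differences sums to 1 and matches
        exact binomial ratios."""
        for N in (8, 15, 25):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, n + K - N), min(n, K)
                    assert log_hypergeom_tail(N, K, n, lo) == 0.0
                    tails = [hypergeom_tail_p(N, K, n, k) for k in range(lo, hi + 1)] + [0.0]
                    pmf = [a - b for a, b in zip(tails, tails[1:])]
                    assert sum(pmf) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        N, K, n = 500, 40, 80
        tails = [hypergeom_tail_p(N, K, n, k) for k in range(0, min(n, K) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_log_space_survives_extreme_overlap(self):
        # overlap far into the tail: p underflows double precision but the
        # log-space value stays finite and negative
        log_tail = log_hypergeom_tail(20000, 500, 500, 450)
        assert math.isfinite(log_tail) and log_tail < math.log(1e-300)

    @pytest.mark.parametrize("bad", [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (10, 5, 5, -1)])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            hypergeom_tail_p(*bad)


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.01]) == [0.01]

    def test_ties_unchanged(self):
        assert bh_fdr([0.02, 0.02, 0.02]) == pytest.approx([0.02, 0.02, 0.02])

    def test_against_definition_oracle(self):
        p = [0.01, 0.04, 0.03, 0.005]
        assert bh_fdr(p) == pytest.approx(bh_definition(p), rel=1e-12)

    def test_against_definition_oracle_random(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40))).tolist()
            assert bh_fdr(p) == pytest.approx(bh_definition(p), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(DomainError):
            bh_fdr([1.5])


def collection_of(sets: dict[str, set[str]]) -> GeneSetCollection:
    return GeneSetCollection(GeneSet(name, "d", frozenset(m)) for name, m in sets.items())


class TestOverlapAnalysis:
    def test_selection_equals_universe_forces_k_equals_K_and_p_one(self):
        universe = {f"G{i}" for i in range(30)}
        coll = collection_of({"S1": {f"G{i}" for i in range(10)}, "S2": {f"G{i}" for i in range(5, 25)}})
        results = overlap_analysis(sorted(universe), coll, universe, min_geneset_size=1)
        for r in results:
            assert r.observed_overlap == r.geneset_size_in_universe
            assert r.p_value == pytest.approx(1.0)

    def test_planted_overlap_matches_monte_carlo_resampling(self):
        """p for a fully captured 10-gene set in a 20/100 selection, checked
        against >= 1e5 random 20-subsets."""
        universe = {f"G{i:03d}" for i in range(100)}
        planted = {f"G{i:03d}" for i in range(10)}
        selection = sorted(planted) + [f"G{i:03d}" for i in range(50, 60)]
        coll = collection_of({"P": planted})
        (r,) = overlap_analysis(selection, coll, universe)
        assert r.observed_overlap == 10
        assert r.expected_overlap == pytest.approx(20 * 10 / 100)

        rng = np.random.default_rng(123)
        draws = 200_000
        idx = np.argpartition(rng.random((draws, 100)), 20, axis=1)[:, :20]
        k_mc = (idx < 10).sum(axis=1)
        p_hat = float(np.mean(k_mc >= 10))
        se = math.sqrt(max(r.p_value * (1 - r.p_value), 1e-30) / draws)
        assert abs(p_hat - r.p_value) <= 3 * se + 1e-12

    def test_sets_outside_size_bounds_skipped(self):
        universe = {f"G{i}" for i in range(100)}
        coll = collection_of(
            {
                "TINY": {"G1", "G2"},
                "OK": {f"G{i}" for i in range(20)},
                "DISJOINT": {"X1", "X2", "X3", "X4", "X5", "X6"},  # K = 0 in universe
            }
        )
        results = overlap_analysis([f"G{i}" for i in range(10)], coll, universe, min_geneset_size=5)
        assert [r.geneset_name for r in results] == ["OK"]

    def test_sorted_by_p_then_k_then_name(self):
        universe = {f"G{i}" for i in range(60)}
        selection = [f"G{i}" for i in range(20)]
        coll = collection_of(
            {
                "B_HIT": {f"G{i}" for i in range(10)},  # strong overlap
                "A_MISS": {f"G{i}" for i in range(40, 50)},  # no overlap
                "C_MISS": {f"G{i}" for i in range(50, 60)},  # no overlap, tie with A
            }
        )
        results = overlap_analysis(selection, coll, universe)
        assert [r.geneset_name for r in results] == ["B_HIT", "A_MISS", "C_MISS"]

    def test_expected_overlap_formula_everywhere(self):
        rng = np.random.default_rng(31)
        genes = [f"G{i}" for i in range(200)]
        universe = set(genes)
        coll = collection_of(
            {f"S{j}": set(rng.choice(genes, size=30, replace=False)) for j in range(10)}
        )
        selection = list(rng.choice(genes, size=50, replace=False))
        for r in overlap_analysis(selection, coll, universe):
            assert r.expected_overlap == pytest.approx(
                r.selection_size * r.geneset_size_in_universe / r.universe_size
            )
            assert r.neg_log10_p == pytest.approx(-math.log10(r.p_value), rel=1e-9)

    def test_selection_ids_outside_universe_dropped_with_warning(self, caplog):
        universe = {f"G{i}" for i in range(20)}
        coll = collection_of({"S": {f"G{i}" for i in range(8)}})
        with caplog.at_level("WARNING", logger="scattergate.enrichment"):
            (r,) = overlap_analysis(["G1", "G2", "NOT_THERE"], coll, universe)
        assert r.selection_size == 2
        assert any("dropped" in rec.message for rec in caplog.records)

    def test_empty_selection_returns_empty_list(self, caplog):
        universe = {"G1", "G2", "G3"}
        coll = collection_of({"S": {"G1"}})
        with caplog.at_level("WARNING", logger="scattergate.enrichment"):
            assert overlap_analysis([], coll, universe) == []

    def test_empty_universe_is_domain_error(self):
        with pytest.raises(DomainError):
            overlap_analysis(["G1"], collection_of({"S": {"G1"} | {f"X{i}" for i in range(5)}}), set())

    def test_planted_set_ranks_first_with_small_q(self, l_shape):
        table, collection = l_shape
        selection = list(l_shape.strata["high_expression"])
        results = overlap_analysis(selection, collection, table.universe())
        assert results[0].geneset_name == "ACTIVE_PATHWAY"
        assert results[0].q_value < 0.05
        silenced = next(r for r in results if r.geneset_name == "SILENCED_PATHWAY")
        assert silenced.p_value > 0.05
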