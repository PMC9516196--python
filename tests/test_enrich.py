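"""Fisher term tests against an exhaustive tail-sum oracle; permutation
correction determinism, bounds, and equivalence with naive recomputation."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from mutpool.degsim import AnnotationSimSpec, PlantedTerm, gene_universe, simulate_annotations
from mutpool.enrich import (
    background_from_counts,
    enrichment_analysis,
    fisher_term_test,
    permutation_correct,
    significant_terms,
    term_table,
    term_tests,
)


def hypergeom_tail_oracle(k, n_bg, n_term, n_deg):
    """Exhaustive tail sums with exact integer combinatorics."""
    denom = math.comb(n_bg, n_deg)
    upper = sum(
        math.comb(n_term, j) * math.comb(n_bg - n_term, n_deg - j)
        for j in range(k, min(n_term, n_deg) + 1)
    ) / denom
    lower = sum(
        math.comb(n_term, j) * math.comb(n_bg - n_term, n_deg - j)
        for j in range(0, k + 1)
    ) / denom
    return upper, lower


def make_sets(n_bg, n_term, n_deg, k, prefix="g"):
    bg = [f"{prefix}{i}" for i in range(n_bg)]
    term = set(bg[:n_term])
    deg = set(bg[:k]) | set(bg[n_term : n_term + n_deg - k])
    assert len(deg & term) == k and len(deg) == n_deg
    return deg, term, set(bg)


class TestFisherOracle:
    def test_enriched_worked_case(self):
        deg, term, bg = make_sets(100, 10, 10, 5)
        p, direction = fisher_term_test(deg, term, bg)
        upper, _ = hypergeom_tail_oracle(5, 100, 10, 10)
        assert p == pytest.approx(upper, rel=1e-9)
        assert direction == "enriched"

    def test_depleted_zero_overlap(self):
        deg, term, bg = make_sets(100, 30, 10, 0)
        p, direction = fisher_term_test(deg, term, bg)
        _, lower = hypergeom_tail_oracle(0, 100, 30, 10)
        assert p == pytest.approx(lower, rel=1e-9)
        assert direction == "depleted"

    def test_term_equals_background(self):
        deg, term, bg = make_sets(50, 50, 10, 10)
        p, _ = fisher_term_test(deg, term, bg)
        assert p == 1.0

    def test_empty_term_intersection_undefined(self):
        bg = {f"g{i}" for i in range(20)}
        p, direction = fisher_term_test(set(list(bg)[:5]), {"x1", "x2"}, bg)
        assert p == 1.0 and direction == "undefined"

    def test_deg_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_term_test({"a"}, {"a"}, {"b"})

    def test_1000_random_tables_match_oracle(self):
        """Smaller one-sided tail equals the exhaustive sum, and agrees with
        scipy's Fisher exact as an independent cross-check."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n_bg = int(rng.integers(10, 80))
            n_term = int(rng.integers(1, n_bg + 1))
            n_deg = int(rng.integers(1, n_bg + 1))
            k_max = min(n_term, n_deg)
            k_min = max(0, n_term + n_deg - n_bg)
            k = int(rng.integers(k_min, k_max + 1))
            deg, term, bg = make_sets(n_bg, n_term, n_deg, k)
            p, direction = fisher_term_test(deg, term, bg)
            upper, lower = hypergeom_tail_oracle(k, n_bg, n_term, n_deg)
            assert p == pytest.approx(min(upper, lower), rel=1e-9, abs=1e-12)
            a, b, c, d = term_table(deg, term, bg)
            assert a + b + c + d == n_bg
            alt = "greater" if direction == "enriched" else "less"
            if upper != lower:
                assert p == pytest.approx(
                    fisher_exact([[a, b], [c, d]], alternative=alt)[1], rel=1e-6
                )


@pytest.fixture(scope="module")
def small_case():
    universe = gene_universe(200)
    rng = np.random.default_rng(1)
    deg = set(rng.choice(universe, 30, replace=False))
    spec = AnnotationSimSpec(n_terms=8, term_size_range=(10, 40), seed=1)
    ann = simulate_annotations(spec, universe)
    return deg, ann, set(universe)


class TestPermutationCorrection:
    def test_deterministic_under_seed(self, small_case):
        deg, ann, bg = small_case
        obs = term_tests(deg, ann, bg)
        c1 = permutation_correct(obs, len(deg), bg, ann, n_perm=10, seed=3)
        c2 = permutation_correct(obs, len(deg), bg, ann, n_perm=10, seed=3)
        assert [r.corrected_p for r in c1] == [r.corrected_p for r in c2]

    def test_corrected_p_bounds(self, small_case):
        deg, ann, bg = small_case
        obs = term_tests(deg, ann, bg)
        res = permutation_correct(obs, len(deg), bg, ann, n_perm=50, seed=2)
        for r in res:
            assert 1 / 51 <= r.corrected_p <= 1.0

    def test_add_one_boundary(self):
        """An observed P smaller than every permuted P gives 1/(n_perm+1)."""
        universe = gene_universe(500)
        deg = set(universe[:50])
        ann = {"T": frozenset(universe[:50])}  # term == DEG set: overlap 50
        obs = term_tests(deg, ann, set(universe))
        res = permutation_correct(obs, 50, set(universe), ann, n_perm=1000, seed=0)
        assert res[0].corrected_p == pytest.approx(1 / 1001)

    def test_matches_naive_recomputation(self, small_case):
        """The vectorized count-lookup path equals per-permutation calls to
        fisher_term_test with the same drawn gene sets."""
        deg, ann, bg = small_case
        obs = term_tests(deg, ann, bg)
        n_perm, seed = 25, 11
        fast = permutation_correct(obs, len(deg), bg, ann, n_perm=n_perm, seed=seed)

        bg_sorted = sorted(bg)
        rng = np.random.default_rng(seed)
        perm_sets = []
        for _ in range(n_perm):
            idx = rng.choice(len(bg_sorted), size=len(deg), replace=False)
            perm_sets.append({bg_sorted[i] for i in idx})
        for t, r in enumerate(obs):
            count = sum(
                fisher_term_test(s, ann[r.term_id], bg)[0] <= r.fisher_p
                for s in perm_sets
            )
            expected = (1 + count) / (1 + n_perm)
            assert fast[t].corrected_p == pytest.approx(expected)

    def test_deg_size_validation(self, small_case):
        deg, ann, bg = small_case
        obs = term_tests(deg, ann, bg)
        with pytest.raises(ValueError):
            permutation_correct(obs, len(bg) + 1, bg, ann, n_perm=5, seed=0)


class TestSignificantTerms:
    def test_strict_threshold_and_sorting(self):
        universe = gene_universe(300)
        deg = set(universe[:40])
        # B overlaps the DEG set at close to its null expectation (5/40)
        ann = {
            "A": frozenset(universe[:40]),
            "B": frozenset(universe[35:75]),
        }
        res = enrichment_analysis(deg, ann, set(universe), n_perm=99, seed=5)
        by_id = {r.term_id: r for r in res}
        sig = significant_terms(res, alpha=0.05)
        assert [r.term_id for r in sig] == ["A"]
        # boundary: exactly alpha is excluded
        assert not significant_terms(res, alpha=by_id["A"].corrected_p)

    def test_requires_correction(self):
        universe = gene_universe(50)
        obs = term_tests(set(universe[:5]), {"T": frozenset(universe[:10])}, set(universe))
        with pytest.raises(ValueError):
            significant_terms(obs)


class TestAnnotationSimulator:
    def test_whole_universe_term_has_p_one(self):
        universe = gene_universe(100)
        ann = {"ALL": frozenset(universe)}
        p, _ = fisher_term_test(set(universe[:10]), ann["ALL"], set(universe))
        assert p == 1.0

    def test_planted_term_oversamples_target(self):
        universe = gene_universe(5000)
        rng = np.random.default_rng(2)
        target = set(rng.choice(universe, 200, replace=False))
        spec = AnnotationSimSpec(
            n_terms=1, term_size_range=(50, 50),
            planted=(PlantedTerm("T", 5.0, 50),), seed=2,
        )
        overlaps = []
        for seed in range(30):
            ann = simulate_annotations(
                AnnotationSimSpec(n_terms=1, term_size_range=(50, 50),
                                  planted=(PlantedTerm("T", 5.0, 50),), seed=seed),
                universe, target_genes=target,
            )
            overlaps.append(len(ann["T"] & target))
        # null expectation 2 genes; planted 5x expectation is 10
        assert 8 < np.mean(overlaps) < 12

    def test_term_size_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotations(
                AnnotationSimSpec(n_terms=1, term_size_range=(20, 20), seed=0),
                gene_universe(10),
            )

    def test_deterministic_under_seed(self):
        universe = gene_universe(200)
        spec = AnnotationSimSpec(n_terms=5, term_size_range=(5, 20), seed=6)
        assert simulate_annotations(spec, universe) == simulate_annotations(spec, universe)


def test_background_from_counts_floor():
    counts = {"a": 0, "b": 1, "c": 2, "d": 30}
    assert background_from_counts(counts) == {"c", "d"}
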