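"""Cumulative curves, the AUC statistic and the permutation null."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from priocost.costbenefit import (
    auc,
    cost_benefit_arrays,
    cumulative_curve,
    mean_null_auc_exact,
    optimal_order,
    permutation_test,
)
from priocost.data_io import SpeciesTable

from conftest import make_record, random_table

# Band map giving species costs 1 and 9 for bands 1 and 5: small worked
# examples with hand-checkable trapezoids.
TOY_BANDS = {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0, 5: 9.0}


def two_species_table() -> SpeciesTable:
    cheap = make_record("cheap", rm_cost=1, ra_spread=1, ra_impact=1)  # cost 1, benefit 1
    dear = make_record("dear", rm_cost=5, ra_spread=1, ra_impact=1)  # cost 9, benefit 1
    return SpeciesTable([cheap, dear])


class TestCumulativeCurve:
    def test_single_species_is_the_diagonal(self):
        table = SpeciesTable([make_record("only")])
        curve = cumulative_curve(["only"], table)
        assert np.allclose(curve.normalized_points, [[0, 0], [1, 1]])
        assert auc(curve) == pytest.approx(0.5)

    def test_two_species_hand_arithmetic(self):
        curve = cumulative_curve(["cheap", "dear"], two_species_table(), TOY_BANDS)
        assert np.allclose(curve.normalized_points, [[0, 0], [0.1, 0.5], [1, 1]])
        assert auc(curve) == pytest.approx(0.7)  # 0.1*0.25 + 0.9*0.75

    def test_reversed_order_reflects_the_area(self):
        curve = cumulative_curve(["dear", "cheap"], two_species_table(), TOY_BANDS)
        assert auc(curve) == pytest.approx(0.3)

    def test_endpoints_and_monotonicity_for_any_order(self, rng):
        table = random_table(rng, 9)
        order = list(table.names)
        rng.shuffle(order)
        curve = cumulative_curve(order, table)
        norm = curve.normalized_points
        assert np.allclose(norm[0], [0, 0])
        assert np.allclose(norm[-1], [1, 1])
        assert np.all(np.diff(norm[:, 0]) >= 0)
        assert np.all(np.diff(norm[:, 1]) >= 0)

    def test_order_must_be_a_permutation(self, mid_table):
        with pytest.raises(ValueError, match="unknown species"):
            cumulative_curve(["alpha", "bravo", "zeta"], mid_table)
        with pytest.raises(ValueError, match="not a permutation"):
            cumulative_curve(["alpha", "alpha", "bravo"], mid_table)


class TestAucProperties:
    def test_reversal_identity_random_tables(self, rng):
        for _ in range(50):
            table = random_table(rng, int(rng.integers(2, 12)))
            order = list(table.names)
            rng.shuffle(order)
            fwd = auc(cumulative_curve(order, table))
            bwd = auc(cumulative_curve(order[::-1], table))
            assert fwd + bwd == pytest.approx(1.0, abs=1e-12)

    def test_auc_invariant_to_uniform_rescaling(self, rng):
        table = random_table(rng, 8)
        order = list(table.names)
        rng.shuffle(order)
        base = auc(cumulative_curve(order, table))
        scaled_bands = {k: v * 1e3 for k, v in TOY_BANDS.items()}
        assert auc(cumulative_curve(order, table, TOY_BANDS)) == pytest.approx(
            auc(cumulative_curve(order, table, scaled_bands)), abs=1e-12
        )
        assert 0.0 <= base <= 1.0

    def test_equal_densities_pin_every_order_to_half(self):
        # benefit proportional to cost: every cumulative curve lies on the diagonal
        records = [
            make_record("a", rm_cost=1, ra_spread=1, ra_impact=1),
            make_record("b", rm_cost=2, ra_spread=1, ra_impact=2),
            make_record("c", rm_cost=3, ra_spread=1, ra_impact=3),
        ]
        table = SpeciesTable(records)
        bands = {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0, 5: 5.0}
        for order in itertools.permutations(table.names):
            assert auc(cumulative_curve(order, table, bands)) == pytest.approx(0.5)


class TestExactNullMean:
    @pytest.mark.parametrize("n", [1, 2, 4, 6])
    def test_mean_over_all_permutations_is_half(self, rng, n):
        if n == 1:
            table = SpeciesTable([make_record("solo")])
        else:
            table = random_table(rng, n)
        assert mean_null_auc_exact(table) == pytest.approx(0.5, abs=1e-12)

    def test_enumeration_refuses_large_tables(self, rng):
        with pytest.raises(ValueError, match="enumeration"):
            mean_null_auc_exact(random_table(rng, 9))


class TestOptimalOrder:
    def test_dominant_species_first(self):
        table = SpeciesTable(
            [
                make_record("low", rm_cost=1, ra_spread=1, ra_impact=1),
                make_record("high", rm_cost=1, ra_spread=5, ra_impact=1),
            ]
        )
        assert optimal_order(table)[0] == "high"

    def test_matches_bruteforce_maximum(self, rng):
        for _ in range(20):
            table = random_table(rng, int(rng.integers(2, 7)))
            best = auc(cumulative_curve(optimal_order(table), table))
            brute = max(
                auc(cumulative_curve(order, table))
                for order in itertools.permutations(table.names)
            )
            assert best == pytest.approx(brute, abs=1e-9)

    def test_greedy_curve_is_concave(self, rng):
        table = random_table(rng, 10)
        norm = cumulative_curve(optimal_order(table), table).normalized_points
        slopes = np.diff(norm[:, 1]) / np.diff(norm[:, 0])
        assert np.all(np.diff(slopes) <= 1e-9)


class TestPermutationTest:
    def test_best_order_boundary_p(self, rng):
        table = random_table(rng, 8)
        result = permutation_test(table, optimal_order(table), n_perm=100, seed=5)
        exceed = int(np.sum(result.null_aucs >= result.observed_auc))
        assert result.p_hat == pytest.approx((1 + exceed) / 101)
        assert exceed <= 2  # the optimum is (almost) never drawn at random

    def test_worst_order_gives_p_one(self, rng):
        table = random_table(rng, 8)
        worst = optimal_order(table)[::-1]
        worst_auc = auc(cumulative_curve(worst, table))
        # the reversed greedy order minimises the AUC, so every null draw exceeds it
        result = permutation_test(table, worst, n_perm=100, seed=5)
        assert result.observed_auc == pytest.approx(worst_auc)
        assert result.p_hat == pytest.approx(1.0)

    def test_lower_tail_alternative_mirrors_upper(self, rng):
        table = random_table(rng, 8)
        order = optimal_order(table)[::-1]
        low = permutation_test(table, order, n_perm=200, seed=9, alternative="less")
        assert low.p_hat < 0.1

    def test_ci_contains_estimate_and_is_ordered(self, rng):
        table = random_table(rng, 10)
        order = list(table.names)
        rng.shuffle(order)
        result = permutation_test(table, order, n_perm=300, seed=17)
        lo, hi = result.p_ci
        assert 0.0 <= lo <= hi <= 1.0
        exceed_rate = np.mean(result.null_aucs >= result.observed_auc)
        assert lo - 1e-12 <= exceed_rate <= hi + 1e-12

    def test_same_seed_reproduces_null_sample(self, rng):
        table = random_table(rng, 8)
        order = list(table.names)
        a = permutation_test(table, order, n_perm=50, seed=3)
        b = permutation_test(table, order, n_perm=50, seed=3)
        assert np.array_equal(a.null_aucs, b.null_aucs)

    def test_invalid_arguments(self, mid_table):
        with pytest.raises(ValueError):
            permutation_test(mid_table, mid_table.names, n_perm=0, seed=1)
        with pytest.raises(ValueError):
            permutation_test(mid_table, mid_table.names, n_perm=10, seed=1, alternative="both")
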