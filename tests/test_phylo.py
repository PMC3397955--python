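import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    oracle_moran_permutation_mean,
    oracle_moran_permutation_p,
    oracle_rank_sum_w,
    oracle_spearman,
)
from msat.phylo import (
    CladePartition,
    TreeValidationError,
    UndefinedStatisticError,
    clades_at_cutoff,
    correlogram,
    default_cutoffs,
    load_tree,
    morans_i,
    morans_i_from_weights,
    node_ages,
    partition_weights,
    spearman_rho,
    wilcoxon_rank_sum,
)


def leaf_sets(part):
    return sorted(frozenset(c) for c in part.clades())


class TestTreeValidation:
    def test_node_ages(self, balanced_tree):
        ages = sorted(node_ages(balanced_tree).values())
        assert ages == pytest.approx([0, 0, 0, 0, 10, 10, 100])

    def test_non_ultrametric_rejected(self):
        tree = load_tree("((a:10,b:30):90,(c:10,d:10):90);")
        with pytest.raises(TreeValidationError):
            node_ages(tree)

    def test_tolerates_tiny_error(self):
        tree = load_tree("((a:10.0000001,b:10):90,(c:10,d:10):90);")
        node_ages(tree)  # within 1e-6 relative tolerance


class TestCladesAtCutoff:
    def test_cutoff_above_root_single_clade(self, balanced_tree):
        part = clades_at_cutoff(balanced_tree, 150)
        assert part.n_clades == 1
        assert leaf_sets(part) == [frozenset("abcd")]

    def test_cherries_at_50(self, balanced_tree):
        part = clades_at_cutoff(balanced_tree, 50)
        assert part.n_clades == 2
        assert leaf_sets(part) == [frozenset("ab"), frozenset("cd")]

    def test_singletons_below_cherry_age(self, balanced_tree):
        part = clades_at_cutoff(balanced_tree, 5)
        assert part.n_clades == 4
        assert leaf_sets(part) == [frozenset(x) for x in "abcd"]

    def test_younger_than_is_strict(self, balanced_tree):
        # cherries sit exactly at age 10: cutoff 10 must not pool them
        part = clades_at_cutoff(balanced_tree, 10)
        assert part.n_clades == 4

    def test_mixed_depth_tree(self):
        tree = load_tree("(((a:10,b:10):40,c:50):250,(d:120,e:120):180);")
        part = clades_at_cutoff(tree, 100)
        assert leaf_sets(part) == [frozenset("abc"), frozenset("d"), frozenset("e")]

    def test_partition_covers_all_leaves(self, balanced_tree):
        for cutoff in (5, 10, 20, 50, 99, 100, 101, 1000):
            part = clades_at_cutoff(balanced_tree, cutoff)
            assert sorted(part.clade_of) == ["a", "b", "c", "d"]

    def test_clade_count_non_increasing_in_cutoff(self):
        from msat.simulate import TraitSimConfig, simulate_yule_tree

        tree = simulate_yule_tree(TraitSimConfig(n_leaves=25, root_age_mya=500, seed=3))
        counts = [clades_at_cutoff(tree, c).n_clades for c in (10, 50, 100, 300, 501)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1

    def test_invalid_cutoff(self, balanced_tree):
        with pytest.raises(ValueError):
            clades_at_cutoff(balanced_tree, 0)


def two_cherry_partition():
    return CladePartition(
        cutoff_mya=50, clade_of={"a": 0, "b": 0, "c": 1, "d": 1}, n_clades=2
    )


class TestMoransI:
    def test_hand_example_perfect_autocorrelation(self):
        pt = morans_i({"a": 1.0, "b": 1.0, "c": 2.0, "d": 2.0}, two_cherry_partition())
        assert pt.I == pytest.approx(1.0)
        assert pt.expected_I == pytest.approx(-1 / 3)
        assert pt.n_species == 4
        assert pt.n_clades == 2

    def test_permutation_mean_equals_expectation(self):
        part = two_cherry_partition()
        w = partition_weights(part, ["a", "b", "c", "d"])
        mean = oracle_moran_permutation_mean([1.0, 2.0, 3.0, 5.0], w)
        assert mean == pytest.approx(-1 / 3, abs=1e-12)

    def test_affine_invariance(self):
        part = two_cherry_partition()
        values = {"a": 1.3, "b": 0.9, "c": 2.5, "d": 2.2}
        base = morans_i(values, part)
        scaled = morans_i({k: 4.0 * v + 7.0 for k, v in values.items()}, part)
        assert scaled.I == pytest.approx(base.I, rel=1e-12)
        assert scaled.sd_I == pytest.approx(base.sd_I, rel=1e-12)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_all_singletons_undefined(self):
        part = CladePartition(10, {"a": 0, "b": 1, "c": 2}, 3)
        with pytest.raises(UndefinedStatisticError):
            morans_i({"a": 1.0, "b": 2.0, "c": 3.0}, part)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            morans_i({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}, two_cherry_partition())

    def test_missing_species_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            morans_i({"a": 1.0, "b": 2.0}, two_cherry_partition())

    def test_singleton_rows_keep_n(self):
        # singletons contribute to the denominator only; n stays the species count
        part = CladePartition(10, {"a": 0, "b": 0, "c": 1, "d": 2}, 3)
        pt = morans_i({"a": 1.0, "b": 1.2, "c": 5.0, "d": 0.2}, part)
        assert pt.n_species == 4
        assert pt.expected_I == pytest.approx(-1 / 3)

    def test_full_weights_give_expectation_exactly(self, rng):
        # one clade containing everyone: I collapses to -1/(n-1) identically
        n = 11
        part = CladePartition(1000, {f"s{i}": 0 for i in range(n)}, 1)
        values = {f"s{i}": float(rng.normal()) for i in range(n)}
        pt = morans_i(values, part)
        assert pt.I == pytest.approx(-1 / (n - 1), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_p_value_agrees_with_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        clades = rng.integers(0, 5, n)
        part = CladePartition(10, {f"s{i}": int(c) for i, c in enumerate(clades)}, 5)
        order = sorted(part.clade_of)
        base = rng.normal(size=5)[clades]  # clade-structured signal
        x = base + rng.normal(scale=1.0, size=n)
        values = {f"s{i}": float(x[i]) for i in range(n)}
        pt = morans_i(values, part)
        w = partition_weights(part, order)
        xv = np.array([values[s] for s in order])
        p_perm = oracle_moran_permutation_p(xv, w, n_perm=10_000, rng=rng)
        # the Gaussian null is an approximation: at n=20 it tracks the
        # permutation distribution to a few hundredths, beyond pure MC error
        mc_sd = math.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 10_000)
        assert pt.p_value == pytest.approx(p_perm, abs=max(0.04, 5 * mc_sd))


class TestCorrelogram:
    def test_default_cutoffs(self):
        assert default_cutoffs(250) == [50, 100, 200, 300]
        assert default_cutoffs(900) == [50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]

    def test_constant_values_all_undefined(self, balanced_tree):
        values = {s: 2.0 for s in "abcd"}
        points = correlogram(balanced_tree, values, [50, 150])
        assert [p.is_defined for p in points] == [False, False]
        assert [p.cutoff_mya for p in points] == [50, 150]

    def test_points_per_cutoff(self, balanced_tree):
        values = {"a": 1.0, "b": 1.1, "c": 3.0, "d": 3.2}
        points = correlogram(balanced_tree, values, [50, 150])
        assert len(points) == 2
        assert points[0].I == pytest.approx(1.0, abs=0.1)
        assert points[1].I == pytest.approx(-1 / 3, abs=1e-12)

    def test_undefined_points_not_dropped(self, balanced_tree):
        values = {"a": 1.0, "b": 1.1, "c": 3.0, "d": 3.2}
        points = correlogram(balanced_tree, values, [5, 50])  # 5 → all singletons
        assert not points[0].is_defined
        assert points[1].is_defined


class TestWilcoxon:
    def test_all_below(self):
        w, _ = wilcoxon_rank_sum([1, 2, 3], [4, 5])
        assert w == 0.0

    def test_all_above(self):
        w, _ = wilcoxon_rank_sum([5, 6], [1, 2, 3])
        assert w == 6.0

    def test_identical_multisets(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert w == 4.5  # |x||y|/2
        assert p == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    def test_matches_pair_enumeration_oracle(self, x, y):
        w, _ = wilcoxon_rank_sum(x, y)
        assert w == pytest.approx(oracle_rank_sum_w(x, y))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=15),
        st.lists(st.floats(-100, 100), min_size=1, max_size=15),
    )
    def test_orientation_identity(self, x, y):
        wxy, _ = wilcoxon_rank_sum(x, y)
        wyx, _ = wilcoxon_rank_sum(y, x)
        assert wxy + wyx == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_perfect_increase(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfect_decrease(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0]
        y = [2.0, 2.0, 1.0, 4.0, 4.0, 6.0, 7.0]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(st.integers(0, 6), min_size=3, max_size=20).filter(
            lambda v: len(set(v)) > 1
        ),
        st.lists(st.integers(0, 6), min_size=3, max_size=20).filter(
            lambda v: len(set(v)) > 1
        ),
    )
    def test_random_ties_match_oracle(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if len(set(x)) < 2 or len(set(y)) < 2 or n < 3:
            return
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])
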