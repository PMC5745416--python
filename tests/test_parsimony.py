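"""Parsimony scoring: Fitch/Sankoff lengths, step bounds, retention indices."""

import numpy as np
import pytest

import phylopart as pp
from phylopart import simulate
from conftest import random_column
from oracles import brute_force_length


class TestCharacterLength:
    def test_constant_column_scores_zero(self, quartet):
        col = pp.CharacterColumn((0, 0, 0, 0))
        assert pp.character_length(quartet, list("ABCD"), col) == 0

    def test_all_distinct_states_forces_n_minus_1(self, quartet):
        col = pp.CharacterColumn((0, 1, 2, 3))
        assert pp.character_length(quartet, list("ABCD"), col) == 3

    def test_perfect_split_costs_one(self, quartet, quartet_alt):
        col = pp.CharacterColumn((0, 0, 1, 1))  # A,B vs C,D
        assert pp.character_length(quartet, list("ABCD"), col) == 1
        assert pp.character_length(quartet_alt, list("ABCD"), col) == 2

    def test_missing_cells_are_unconstrained(self, quartet):
        col = pp.CharacterColumn((0, None, 1, None))
        assert pp.character_length(quartet, list("ABCD"), col) == 1

    def test_ordered_linear_cost(self, quartet):
        col = pp.CharacterColumn((0, 0, 2, 2))
        assert pp.character_length(
            quartet, list("ABCD"), col, ordering="ordered"
        ) == 2

    def test_matches_bruteforce_on_random_instances(self, rng):
        """Random 5-6 taxon columns vs exhaustive internal-labeling search."""
        for _ in range(25):
            n = int(rng.integers(5, 7))
            tree = simulate.simulate_tree(n, rng)
            taxa = sorted(tree.leaf_labels)
            col = random_column(rng, n)
            for ordering in ("unordered", "ordered"):
                assert pp.character_length(tree, taxa, col, ordering) == \
                    brute_force_length(tree, taxa, col, ordering)

    def test_scoring_invariant_to_rerooting(self, rng):
        tree = simulate.simulate_tree(7, rng)
        taxa = sorted(tree.leaf_labels)
        col = random_column(rng, 7)
        base = pp.character_length(tree, taxa, col)
        for leaf in taxa:
            assert pp.character_length(tree.reroot_at(leaf), taxa, col) == base

    def test_scoring_invariant_to_matrix_taxon_order(self, rng):
        tree = simulate.simulate_tree(6, rng)
        taxa = sorted(tree.leaf_labels)
        cells = [int(rng.integers(3)) for _ in taxa]
        col = pp.CharacterColumn(tuple(cells))
        base = pp.character_length(tree, taxa, col)
        perm = rng.permutation(len(taxa))
        taxa2 = [taxa[i] for i in perm]
        col2 = pp.CharacterColumn(tuple(cells[i] for i in perm))
        assert pp.character_length(tree, taxa2, col2) == base

    def test_polytomies_scored_as_hard(self):
        star = pp.PhyloTree.star(list("ABCDEF"))
        col = pp.CharacterColumn((0, 0, 0, 1, 1, 1))
        # on a star no internal structure can absorb the split
        assert pp.character_length(star, list("ABCDEF"), col) == 3

    def test_taxon_missing_from_tree_is_mismatch(self, quartet):
        col = pp.CharacterColumn((0, 0, 1, 1, 1))
        with pytest.raises(pp.TreeMismatchError):
            pp.character_length(quartet, list("ABCDE"), col)

    def test_binary_ordered_equals_unordered(self, rng):
        """Linear cost equals unit cost when only 2 states occur."""
        for _ in range(10):
            tree = simulate.simulate_tree(6, rng)
            taxa = sorted(tree.leaf_labels)
            col = random_column(rng, 6, n_states=2)
            assert pp.character_length(tree, taxa, col, "ordered") == \
                pp.character_length(tree, taxa, col, "unordered")


class TestStepBounds:
    def test_min_steps_counts_distinct_states(self):
        assert pp.min_steps(pp.CharacterColumn((0, 0, 1, 1))) == 1
        assert pp.min_steps(pp.CharacterColumn((0, 1, 2, 0))) == 2

    def test_min_steps_ordered_is_state_span(self):
        col = pp.CharacterColumn((0, 2))
        assert pp.min_steps(col, "ordered") == 2

    def test_min_steps_polymorphic_by_enumeration(self, rng):
        """Union semantics: the best resolution of each polymorphic cell."""
        import itertools

        for _ in range(20):
            col = random_column(rng, 5, p_missing=0.1, p_poly=0.4)
            for ordering in ("unordered", "ordered"):
                live = [c for c in col.cells if c is not None]
                best = None
                for pick in itertools.product(*[sorted(c) for c in live]):
                    resolved = pp.CharacterColumn(tuple(pick))
                    v = pp.min_steps(resolved, ordering)
                    best = v if best is None else min(best, v)
                assert pp.min_steps(col, ordering) == best

    def test_max_steps_is_minority_count(self):
        col = pp.CharacterColumn((0, 0, 0, 0, 1, 1))
        assert pp.max_steps(col) == 2

    def test_max_steps_ordered_weighted_median(self):
        col = pp.CharacterColumn((0, 0, 2, 2))
        assert pp.max_steps(col, "ordered") == 4

    def test_max_steps_equals_star_tree_length(self, rng):
        labels = [f"x{i}" for i in range(6)]
        star = pp.PhyloTree.star(labels)
        for _ in range(20):
            col = random_column(rng, 6, n_states=4, p_poly=0.3)
            for ordering in ("unordered", "ordered"):
                assert pp.max_steps(col, ordering) == \
                    pp.character_length(star, labels, col, ordering)

    def test_all_missing_column_is_undefined(self):
        col = pp.CharacterColumn((None, None, None))
        with pytest.raises(pp.UninformativeCharacterError):
            pp.min_steps(col)

    def test_length_bounded_by_min_and_max(self, rng):
        """m <= s <= g on random binary trees (core RI invariant)."""
        for _ in range(30):
            n = int(rng.integers(5, 9))
            tree = simulate.simulate_tree(n, rng)
            taxa = sorted(tree.leaf_labels)
            col = random_column(rng, n, n_states=4, p_poly=0.2)
            for ordering in ("unordered", "ordered"):
                s = pp.character_length(tree, taxa, col, ordering)
                assert pp.min_steps(col, ordering) <= s
                assert s <= pp.max_steps(col, ordering)


class TestRetentionIndex:
    def test_endpoints(self):
        assert pp.retention_index(1, 1, 5) == 1.0
        assert pp.retention_index(5, 1, 5) == 0.0

    def test_formula(self):
        assert pp.retention_index(2, 1, 5) == pytest.approx(0.75)

    def test_uninformative_character_rejected(self):
        with pytest.raises(pp.UninformativeCharacterError):
            pp.retention_index(1, 1, 1)

    def test_autapomorphy_is_uninformative(self):
        col = pp.CharacterColumn((0, 0, 0, 0, 1))
        assert not pp.is_informative(col)

    def test_informative_indices_match_gm_oracle(self, rng, small_matrix):
        keep = pp.informative_indices(small_matrix)
        for j in range(small_matrix.n_characters):
            col = small_matrix.columns[j]
            o = small_matrix.ordering[j]
            expected = pp.max_steps(col, o) > pp.min_steps(col, o)
            assert (j in keep) == expected


class TestPartitionFit:
    def test_perfect_fit_gives_ri_one(self, rng):
        tree = simulate.simulate_tree(8, rng)
        cols = simulate.simulate_perfect_characters(tree, 12, rng)
        m = pp.CharacterMatrix(
            tuple(sorted(tree.leaf_labels)), tuple(cols),
            ("unordered",) * 12, ("hard",) * 12,
        )
        fit = pp.partition_fit(tree, m)
        assert fit.RI == 1.0
        assert all(f.ri == 1.0 for f in fit.fits)

    def test_single_character_RI_equals_its_ri(self, quartet_alt):
        m = pp.matrix_from_strings(
            list("ABCD"), [[0], [0], [1], [1]], partition=["hard"]
        )
        fit = pp.partition_fit(quartet_alt, m)
        assert fit.RI == fit.fits[0].ri

    def test_ensemble_RI_is_ratio_of_sums(self, rng):
        """Cross-check the ensemble against independent resummation."""
        tree = simulate.simulate_tree(8, rng)
        taxa = sorted(tree.leaf_labels)
        cols = [random_column(rng, 8) for _ in range(10)]
        m = pp.CharacterMatrix(
            tuple(taxa), tuple(cols), ("unordered",) * 10, ("hard",) * 10
        )
        keep = pp.informative_indices(m)
        fit = pp.partition_fit(tree, m)
        ss = sum(pp.character_length(tree, taxa, m.columns[j]) for j in keep)
        sm = sum(pp.min_steps(m.columns[j]) for j in keep)
        sg = sum(pp.max_steps(m.columns[j]) for j in keep)
        assert fit.RI == pytest.approx((sg - ss) / (sg - sm))
        lo = min(f.ri for f in fit.fits)
        hi = max(f.ri for f in fit.fits)
        assert lo - 1e-12 <= fit.RI <= hi + 1e-12

    def test_degenerate_partition_rejected(self, quartet):
        m = pp.matrix_from_strings(
            list("ABCD"), [[0], [0], [0], [1]], partition=["hard"]
        )
        with pytest.raises(pp.DegeneratePartitionError):
            pp.partition_fit(quartet, m)


class TestTreeLength:
    def test_additive_over_disjoint_subsets(self, small_matrix):
        tree = pp.PhyloTree.from_newick("((a,b),(c,(d,(e,f))));")
        la = pp.tree_length(tree, small_matrix, [0, 1])
        lb = pp.tree_length(tree, small_matrix, [2, 3])
        assert pp.tree_length(tree, small_matrix) == la + lb

    def test_matches_per_character_oracle(self, rng):
        tree = simulate.simulate_tree(6, rng)
        taxa = sorted(tree.leaf_labels)
        cols = [random_column(rng, 6) for _ in range(6)]
        m = pp.CharacterMatrix(
            tuple(taxa), tuple(cols),
            ("unordered", "ordered") * 3, ("hard",) * 6,
        )
        total = sum(
            brute_force_length(tree, taxa, m.columns[j], m.ordering[j])
            for j in range(6)
        )
        assert pp.tree_length(tree, m) == total
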