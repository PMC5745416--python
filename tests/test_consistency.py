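"""Molecular-consistency stage: pruning, filtering, RI on reference trees,
and the Mann-Whitney-Wilcoxon comparison."""

import numpy as np
import pytest

import phylopart as pp
from phylopart import simulate
from conftest import random_column
from oracles import exact_mww_p, splits_of_tree


def matrix_on(tree, n_hard=8, n_soft=8, rate=1.0, seed=0, soft_tree=None):
    taxa = sorted(tree.leaf_labels)
    hard = simulate.simulate_characters(tree, n_hard, 3, rate, seed)
    soft = simulate.simulate_characters(
        soft_tree or tree, n_soft, 3, rate, seed + 1
    )
    return pp.CharacterMatrix(
        tuple(taxa), tuple(hard + soft), ("unordered",) * (n_hard + n_soft),
        ("hard",) * n_hard + ("soft",) * n_soft,
    )


class TestPrune:
    def test_identical_leaf_sets_returned_unchanged(self, rng):
        tree = simulate.simulate_tree(12, rng)
        m = matrix_on(tree)
        pm, pt = pp.prune_to_reference(m, tree)
        assert pm is m
        assert pt is tree

    def test_partial_overlap_pruned_to_shared(self, rng):
        tree = simulate.simulate_tree(12, rng)
        m = matrix_on(tree)
        sub = tree.prune_to(sorted(tree.leaf_labels)[:10])
        pm, pt = pp.prune_to_reference(m, sub)
        assert pm.n_taxa == 10
        assert pt.n_leaves == 10

    def test_coverage_rule_mirrors_minimum_ten(self, rng):
        tree = simulate.simulate_tree(12, rng)
        m = matrix_on(tree)
        sub = tree.prune_to(sorted(tree.leaf_labels)[:9])
        with pytest.raises(pp.CoverageError):
            pp.prune_to_reference(m, sub)
        # severity configurable: relaxing the threshold admits the dataset
        pm, pt = pp.prune_to_reference(m, sub, min_shared=8)
        assert pm.n_taxa == 9

    def test_pruned_bipartitions_match_restriction_oracle(self, rng):
        """Splits after pruning = splits of the leaf-set restriction."""
        for _ in range(5):
            tree = simulate.simulate_tree(10, rng)
            keep = sorted(tree.leaf_labels)[:7]
            pruned = tree.prune_to(keep)
            got = splits_of_tree(pruned, sorted(keep))
            full = splits_of_tree(tree, sorted(tree.leaf_labels))
            keepset = frozenset(keep)
            expect = set()
            for side in full:
                r = side & keepset
                if 2 <= len(r) <= len(keep) - 2:
                    opp = keepset - r
                    expect.add(r if sorted(keep)[0] not in r else opp)
            assert got == expect


class TestFilter:
    def test_constant_and_autapomorphic_dropped(self):
        m = pp.matrix_from_strings(
            list("ABCDE"),
            [[0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0], [0, 1, 1]],
            partition=["hard", "hard", "soft"],
        )
        # col0 constant, col1 informative (2+3), col2 informative
        assert pp.filter_informative(m) == (1, 2)

    def test_filter_matches_gm_oracle_on_random(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        cols = [random_column(rng, 8) for _ in range(12)]
        m = pp.CharacterMatrix(
            tuple(taxa), tuple(cols), ("unordered",) * 12,
            ("hard",) * 6 + ("soft",) * 6,
        )
        keep = pp.filter_informative(m)
        for j in range(12):
            informative = pp.max_steps(m.columns[j]) > pp.min_steps(
                m.columns[j]
            )
            assert (j in keep) == informative


class TestMWW:
    def test_complete_separation_three_vs_three(self):
        # 2 of the 20 rank assignments are this extreme: p = 0.1
        assert pp.mww_test([0.1, 0.2, 0.3], [0.7, 0.8, 0.9]) == \
            pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert pp.mww_test([0.5, 0.7], [0.5, 0.7]) == 1.0

    def test_all_tied_input_returns_one(self):
        assert pp.mww_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_matches_exact_enumeration_oracle(self, rng):
        for _ in range(10):
            na, nb = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            vals = rng.permutation(100)[: na + nb].astype(float).tolist()
            a, b = vals[:na], vals[na:]
            assert pp.mww_test(a, b) == pytest.approx(exact_mww_p(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(pp.ValidationError):
            pp.mww_test([], [0.5])


class TestConsistency:
    def test_reference_equals_truth_all_ri_one(self, rng):
        tree = simulate.simulate_tree(10, rng)
        taxa = sorted(tree.leaf_labels)
        cols = simulate.simulate_perfect_characters(tree, 16, rng)
        m = pp.CharacterMatrix(
            tuple(taxa), tuple(cols), ("unordered",) * 16,
            ("hard",) * 8 + ("soft",) * 8,
        )
        res = pp.consistency_test(m, tree)
        assert set(res.ri_hard) == {1.0}
        assert set(res.ri_soft) == {1.0}
        assert res.RI_hard == res.RI_soft == 1.0
        assert res.mww_p == 1.0  # all ties carry no rank information

    def test_directional_difference_detected(self):
        """Soft simulated on the reference, hard on a distant tree:
        RI_soft should exceed RI_hard in the large majority of runs."""
        wins = 0
        small_p = 0
        n = 12
        for k in range(n):
            ref = simulate.simulate_tree(12, 400 + k)
            far = simulate.spr_neighbor(ref, 5, 401 + k)
            m = matrix_on(ref, rate=0.5, seed=402 + k, soft_tree=ref)
            # rebuild: hard from the distant tree, soft from the reference
            hard = simulate.simulate_characters(far, 8, 3, 0.5, 403 + k)
            soft = simulate.simulate_characters(ref, 8, 3, 0.5, 404 + k)
            taxa = sorted(ref.leaf_labels)
            m = pp.CharacterMatrix(
                tuple(taxa), tuple(hard + soft), ("unordered",) * 16,
                ("hard",) * 8 + ("soft",) * 8,
            )
            try:
                res = pp.consistency_test(m, ref)
            except pp.DegeneratePartitionError:
                continue
            wins += res.RI_soft > res.RI_hard
            small_p += res.mww_p <= 0.05
        assert wins >= 9

    def test_ri_invariant_to_reference_rooting(self, rng):
        tree = simulate.simulate_tree(10, rng)
        m = matrix_on(tree, seed=7)
        base = pp.consistency_test(m, tree)
        rerooted = tree.reroot_at(sorted(tree.leaf_labels)[3])
        again = pp.consistency_test(m, rerooted)
        assert base.ri_hard == again.ri_hard
        assert base.RI_soft == again.RI_soft

    def test_matches_parsimony_fit_when_reference_is_mpt(self, rng):
        """Cross-module check: ri on an MPT of the same characters equals
        ri from the parsimony analysis."""
        tree = simulate.simulate_tree(10, rng)
        m = matrix_on(tree, seed=3)
        ts = pp.parsimony_search(
            m, config=pp.SearchConfig(seed=2, rearrangement="spr")
        )
        mpt = ts.trees[0]
        res = pp.consistency_test(m, mpt)
        fit_h = pp.partition_fit(mpt, m, m.hard_indices)
        assert res.ri_hard == tuple(f.ri for f in fit_h.fits)
        assert res.RI_hard == pytest.approx(fit_h.RI)

    def test_counts_are_bookkept(self, rng):
        tree = simulate.simulate_tree(13, rng)
        m = matrix_on(tree, seed=9)
        sub = tree.prune_to(sorted(tree.leaf_labels)[:11])
        res = pp.consistency_test(m, sub)
        assert res.n_taxa_used == 11
        assert res.n_excluded_taxa == 2
        assert res.n_excluded_characters == (
            m.n_characters - len(res.ri_hard) - len(res.ri_soft)
        )
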