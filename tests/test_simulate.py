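"""The synthetic-data generator: distributions, determinism, truth objects."""

import numpy as np
import pytest
from scipy import stats

import phylopart as pp
from phylopart import simulate


class TestSimulateTree:
    def test_same_seed_identical_tree(self):
        a = simulate.simulate_tree(8, 7)
        b = simulate.simulate_tree(8, 7)
        assert a.same_topology(b)
        assert a.to_newick(lengths=True) == b.to_newick(lengths=True)

    def test_ten_taxa_have_seven_nontrivial_splits(self):
        t = simulate.simulate_tree(10, 1)
        assert len(t.bipartition_masks()) == 7

    def test_four_taxon_topologies_uniform(self):
        """Chi-squared goodness of fit over the 3 quartet topologies."""
        rng = np.random.default_rng(99)
        counts = {}
        n = 3000
        for _ in range(n):
            key = simulate.simulate_tree(4, rng).bipartition_masks()
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        chi2 = sum((c - n / 3) ** 2 / (n / 3) for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_unit_mean_depth(self):
        t = simulate.simulate_tree(12, 5)
        dt = t.dendropy_tree
        depths = []
        for lf in dt.leaf_node_iter():
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths.append(d)
        assert np.mean(depths) == pytest.approx(1.0)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(pp.ValidationError):
            simulate.simulate_tree(3, 0)


class TestSprNeighbor:
    def test_zero_moves_is_identity(self):
        t = simulate.simulate_tree(8, 3)
        assert simulate.spr_neighbor(t, 0, 1) is t

    def test_one_move_changes_at_least_one_split(self):
        t = simulate.simulate_tree(8, 3)
        moved = simulate.spr_neighbor(t, 1, 11)
        assert pp.rf_distance(t, moved) >= 2

    def test_moves_never_revisit(self):
        t = simulate.simulate_tree(9, 4)
        seen = {t.topology_key()}
        cur = t
        for k in range(6):
            cur = simulate.spr_neighbor(t, k + 1, 21)
        # k-move walks from one seed share a prefix and never loop back
        keys = {
            simulate.spr_neighbor(t, k, 21).topology_key()
            for k in range(1, 7)
        }
        assert len(keys) == 6

    def test_rf_trend_nondecreasing_in_moves(self):
        """Mean RF from the start grows (weakly) with the move count."""
        rng = np.random.default_rng(8)
        means = []
        for moves in (1, 3, 6):
            ds = []
            for k in range(60):
                t = simulate.simulate_tree(10, 1000 + k)
                ds.append(
                    pp.rf_distance(
                        t, simulate.spr_neighbor(t, moves, 2000 + k)
                    )
                )
            means.append(np.mean(ds))
        assert means[0] <= means[1] <= means[2]


class TestSimulateCharacters:
    def test_rate_zero_all_constant(self):
        t = simulate.simulate_tree(8, 2)
        cols = simulate.simulate_characters(t, 20, 3, 0.0, 3)
        assert all(c.is_constant() for c in cols)

    def test_same_seed_identical_columns(self):
        t = simulate.simulate_tree(8, 2)
        a = simulate.simulate_characters(t, 10, 3, 1.0, 5)
        b = simulate.simulate_characters(t, 10, 3, 1.0, 5)
        assert [c.cells for c in a] == [c.cells for c in b]

    def test_poisson_change_count_expectation(self):
        """Realized substitutions per character ~ rate x total length."""
        t = simulate.simulate_tree(10, 6)
        rate = 1.5
        n_chars = 2000
        _, changes = simulate.simulate_characters(
            t, n_chars, 3, rate, 17, return_changes=True
        )
        expected = rate * t.total_branch_length()
        se = np.sqrt(expected / n_chars)
        assert abs(changes.mean() - expected) < 3 * se

    def test_perfect_characters_have_ri_one(self):
        t = simulate.simulate_tree(9, 12)
        cols = simulate.simulate_perfect_characters(t, 10, 13)
        taxa = sorted(t.leaf_labels)
        for col in cols:
            s = pp.character_length(t, taxa, col)
            assert pp.retention_index(
                s, pp.min_steps(col), pp.max_steps(col)
            ) == 1.0


class TestMasking:
    def test_masking_fraction_within_binomial_tolerance(self):
        t = simulate.simulate_tree(12, 3)
        cols = simulate.simulate_characters(t, 200, 3, 1.0, 4)
        masked = simulate.mask_missing(cols, 0.5, 5)
        n_cells = 12 * 200
        n_missing = sum(
            1 for c in masked for v in c.cells if v is pp.MISSING
        )
        se = np.sqrt(n_cells * 0.25)
        assert abs(n_missing - n_cells / 2) < 4 * se


class TestSimulateDataset:
    def test_homogeneous_construction(self):
        d = simulate.simulate_dataset(
            simulate.SimulationConfig(incongruence=0, seed=4)
        )
        assert d.tree_hard.same_topology(d.tree_soft)
        assert d.matrix.n_characters == 60
        assert len(d.matrix.hard_indices) == 30

    def test_incongruent_trees_are_apart(self):
        d = simulate.simulate_dataset(
            simulate.SimulationConfig(incongruence=5, seed=4)
        )
        assert pp.rf_distance(d.tree_hard, d.tree_soft) >= 2

    def test_soft_fits_reference_better_when_hard_off_tree(self):
        """Mirrors the empirical pattern where one partition is less
        consistent with the molecular benchmark."""
        wins = 0
        n = 12
        for k in range(n):
            d = simulate.simulate_dataset(
                simulate.SimulationConfig(
                    incongruence=5, reference_distortion=0, rate=0.5,
                    seed=3000 + k,
                )
            )
            res = pp.consistency_test(d.matrix, d.reference)
            wins += res.RI_soft > res.RI_hard
        assert wins >= 9

    def test_partition_specific_masking(self):
        d = simulate.simulate_dataset(
            simulate.SimulationConfig(
                missing_hard=0.0, missing_soft=0.5, seed=6
            )
        )
        soft_missing = sum(
            1 for j in d.matrix.soft_indices
            for v in d.matrix.columns[j].cells if v is pp.MISSING
        )
        hard_missing = sum(
            1 for j in d.matrix.hard_indices
            for v in d.matrix.columns[j].cells if v is pp.MISSING
        )
        assert hard_missing == 0
        n_cells = 12 * 30
        se = np.sqrt(n_cells * 0.25)
        assert abs(soft_missing - n_cells / 2) < 4 * se

    def test_deterministic_and_emits_standard_files(self, tmp_path):
        cfg = simulate.SimulationConfig(seed=9)
        a = simulate.simulate_dataset(cfg)
        b = simulate.simulate_dataset(cfg)
        assert [c.cells for c in a.matrix.columns] == [
            c.cells for c in b.matrix.columns
        ]
        # written files are indistinguishable from real pipeline inputs
        pp.write_nexus_matrix(a.matrix, tmp_path / "sim.nex")
        pp.write_newick_tree(a.reference, tmp_path / "sim.nwk")
        m = pp.read_nexus_matrix(tmp_path / "sim.nex")
        t = pp.read_newick_tree(tmp_path / "sim.nwk")
        assert m.taxa == a.matrix.taxa
        assert t.same_topology(a.reference)
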