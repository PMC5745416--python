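"""Synthetic matrices, partitions and reference trees.

The generator emulates the structure of a published morphological
dataset with hard and soft character partitions: discrete characters
evolved on a tree under a symmetric k-state Markov process, two
partitions whose generating trees can be pushed apart by a controlled
number of SPR moves (topological incongruence) and can evolve at
different rates, a "molecular" reference tree derived from the soft
generating tree by further SPR distortion, and missing entries masked
completely at random with partition-specific rates (soft anatomy is the
partition lost to taphonomy in real data).

Defaults describe a modest published matrix: 12 taxa, 30 + 30
characters, 3 states, one expected substitution per character per unit
tree depth, no incongruence, no distortion, no missing data.  Branch
lengths are exponential draws rescaled so the mean root-to-tip path
length is 1, which makes ``rate`` read as expected changes per
character along an average lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _arrays as A
from .characters import (
    HARD,
    MISSING,
    SOFT,
    UNORDERED,
    CharacterColumn,
    CharacterMatrix,
)
from .errors import ValidationError
from .trees import PhyloTree


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_taxa: int = 12
    n_hard: int = 30
    n_soft: int = 30
    n_states: int = 3
    rate: float = 1.0
    rate_soft: float | None = None  # defaults to ``rate``
    incongruence: int = 0  # SPR moves between the generating trees
    reference_distortion: int = 0  # SPR moves soft tree -> reference
    missing_hard: float = 0.0
    missing_soft: float = 0.0
    character_model: str = "mk"  # "mk" | "perfect"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValidationError("n_taxa must be >= 4")
        if self.n_hard < 0 or self.n_soft < 0:
            raise ValidationError("character counts must be >= 0")
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if self.rate < 0:
            raise ValidationError("rate must be >= 0")
        if self.incongruence < 0 or self.reference_distortion < 0:
            raise ValidationError("SPR move counts must be >= 0")
        for f in (self.missing_hard, self.missing_soft):
            if not (0.0 <= f <= 1.0):
                raise ValidationError("missing fractions must be in [0, 1]")
        if self.character_model not in ("mk", "perfect"):
            raise ValidationError("character_model must be 'mk' or 'perfect'")


@dataclass(frozen=True)
class SimulatedDataset:
    """A synthetic dataset together with its generating objects."""

    matrix: CharacterMatrix
    tree_hard: PhyloTree
    tree_soft: PhyloTree
    reference: PhyloTree
    config: SimulationConfig


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _taxon_labels(n: int) -> list:
    width = len(str(n))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def _random_topology_arrays(n: int, rng: np.random.Generator):
    """Uniform unrooted binary topology via random stepwise addition.

    With a fixed insertion order, each topology corresponds to exactly
    one sequence of edge choices, so uniform edge choices give the
    uniform distribution over the ``(2n-5)!!`` labelled topologies.
    """
    par, left, right = A.blank_arrays(n)
    root, w0 = A.init_triplet(par, left, right, 0, 1, 2, n)
    candidates = [1, 2, w0]
    next_internal = n + 1
    for z in range(3, n):
        x = candidates[int(rng.integers(len(candidates)))]
        A.insert_leaf(par, left, right, x, z, next_internal)
        candidates.append(z)
        candidates.append(next_internal)
        next_internal += 1
    return par, left, right, root


def _newick_with_lengths(left, right, root, labels, lengths) -> str:
    def rec(v):
        if left[v] < 0:
            return f"{labels[v]}:{lengths[v]:.10g}"
        return (
            f"({rec(left[v])},{rec(right[v])}):{lengths[v]:.10g}"
        )

    return f"({rec(left[root])},{rec(right[root])});"


def _assign_lengths(left, right, root, labels, rng) -> PhyloTree:
    """Exponential(1) edge lengths rescaled to unit mean root-to-tip depth."""
    M = left.shape[0]
    lengths = rng.exponential(1.0, size=M)
    lengths[root] = 0.0
    # mean root-to-leaf depth
    depth = np.zeros(M)
    total = 0.0
    count = 0
    stack = [root]
    while stack:
        v = stack.pop()
        if left[v] >= 0:
            for c in (left[v], right[v]):
                depth[c] = depth[v] + lengths[c]
                stack.append(c)
        else:
            total += depth[v]
            count += 1
    scale = count / total if total > 0 else 1.0
    lengths *= scale
    return PhyloTree.from_newick(
        _newick_with_lengths(left, right, root, labels, lengths)
    )


def simulate_tree(n_taxa: int, seed=0) -> PhyloTree:
    """Random binary tree: uniform topology, exponential branch lengths
    normalized to unit mean depth."""
    if n_taxa < 4:
        raise ValidationError("n_taxa must be >= 4")
    rng = _as_rng(seed)
    labels = _taxon_labels(n_taxa)
    par, left, right, root = _random_topology_arrays(n_taxa, rng)
    return _assign_lengths(left, right, root, labels, rng)


class _NullCtx:
    """Score-free context so search neighbour generators can enumerate
    SPR moves for the simulator."""

    def __init__(self, n):
        self.n = n
        self.M = 2 * n - 1
        self.root = self.M - 1

    def score(self, left, right):
        return 0


def spr_neighbor(tree: PhyloTree, moves: int, seed=0) -> PhyloTree:
    """Apply random SPR moves, never revisiting an earlier topology.

    ``moves=0`` returns the input unchanged.  Branch lengths of the
    rearranged tree are redrawn (an SPR has no canonical length
    inheritance), again normalized to unit mean depth.
    """
    from .search import _spr_neighbors  # local import avoids a cycle

    if moves < 0:
        raise ValidationError("moves must be >= 0")
    if moves == 0:
        return tree
    rng = _as_rng(seed)
    taxa = sorted(tree.leaf_labels)
    par, left, right, root = A.arrays_from_phylo(tree, taxa)
    n = len(taxa)
    ctx = _NullCtx(n)
    visited = {A.splits_key(par, left, right, root, n)}
    for _ in range(moves):
        neighbors = [
            snap for _, snap in _spr_neighbors(ctx, par, left, right)
        ]
        order = rng.permutation(len(neighbors))
        stepped = False
        for i in order:
            cand = neighbors[int(i)]
            key = A.splits_key(cand[0], cand[1], cand[2], root, n)
            if key not in visited:
                par, left, right = cand
                visited.add(key)
                stepped = True
                break
        if not stepped:  # neighbourhood exhausted (tiny trees)
            break
    return _assign_lengths(left, right, root, taxa, rng)


def simulate_characters(
    tree: PhyloTree,
    n_chars: int,
    n_states: int,
    rate: float,
    seed=0,
    return_changes: bool = False,
):
    """Evolve characters independently under a symmetric Markov model.

    Substitution events arrive as a Poisson process with intensity
    ``rate`` per unit branch length; each event moves to a uniformly
    chosen different state.  The root state is uniform.  Returns one
    :class:`CharacterColumn` per character with cells ordered by
    ``sorted(tree.leaf_labels)``.
    """
    if n_states < 2:
        raise ValidationError("n_states must be >= 2")
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    rng = _as_rng(seed)
    taxa = sorted(tree.leaf_labels)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    cells = np.zeros((n, n_chars), dtype=np.int64)
    root = tree.dendropy_tree.seed_node
    state_of = {id(root): rng.integers(n_states, size=n_chars)}
    change_counts = np.zeros(n_chars, dtype=np.int64)
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd is root:
            continue
        parent_state = state_of[id(nd.parent_node)]
        length = nd.edge.length or 0.0
        events = rng.poisson(rate * length, size=n_chars)
        change_counts += events
        state = parent_state.copy()
        for c in np.nonzero(events)[0]:
            s = state[c]
            for _ in range(events[c]):
                step = rng.integers(1, n_states)
                s = (s + step) % n_states
            state[c] = s
        state_of[id(nd)] = state
        if nd.is_leaf():
            cells[index[nd.taxon.label]] = state
    cols = [
        CharacterColumn(tuple(int(cells[i, c]) for i in range(n)))
        for c in range(n_chars)
    ]
    if return_changes:
        return cols, change_counts
    return cols


def simulate_perfect_characters(tree: PhyloTree, n_chars: int, seed=0) -> list:
    """Homoplasy-free binary characters: one change on one internal edge.

    The zero-rate limit with a single forced change per character; every
    such character has retention index 1 on the generating tree.
    """
    rng = _as_rng(seed)
    taxa = sorted(tree.leaf_labels)
    order = taxa
    splits = sorted(tree.bipartition_masks(order))
    if not splits:
        raise ValidationError("tree has no internal edges (star tree)")
    n = len(taxa)
    cols = []
    for _ in range(n_chars):
        m = splits[int(rng.integers(len(splits)))]
        cols.append(
            CharacterColumn(tuple(int((m >> i) & 1) for i in range(n)))
        )
    return cols


def mask_missing(columns, fraction: float, seed=0) -> list:
    """Mask cells to MISSING independently with the given probability."""
    rng = _as_rng(seed)
    out = []
    for col in columns:
        mask = rng.random(len(col.cells)) < fraction
        out.append(
            CharacterColumn(
                tuple(
                    MISSING if m else c for c, m in zip(col.cells, mask)
                )
            )
        )
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset: matrix, generating trees, reference tree.

    The hard partition evolves on tree T_h; the soft partition on
    T_s = ``incongruence`` SPR moves away; the reference tree is
    ``reference_distortion`` further moves from T_s.  All generating
    objects are returned so tests can assert against the truth.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (s_tree, s_spr1, s_spr2, s_hard, s_soft, s_mask_h, s_mask_s) = ss.spawn(7)
    tree_hard = simulate_tree(cfg.n_taxa, np.random.default_rng(s_tree))
    tree_soft = spr_neighbor(
        tree_hard, cfg.incongruence, np.random.default_rng(s_spr1)
    )
    reference = spr_neighbor(
        tree_soft, cfg.reference_distortion, np.random.default_rng(s_spr2)
    )
    rate_soft = cfg.rate if cfg.rate_soft is None else cfg.rate_soft
    if cfg.character_model == "perfect":
        cols_hard = simulate_perfect_characters(
            tree_hard, cfg.n_hard, np.random.default_rng(s_hard)
        )
        cols_soft = simulate_perfect_characters(
            tree_soft, cfg.n_soft, np.random.default_rng(s_soft)
        )
    else:
        cols_hard = simulate_characters(
            tree_hard, cfg.n_hard, cfg.n_states, cfg.rate,
            np.random.default_rng(s_hard),
        )
        cols_soft = simulate_characters(
            tree_soft, cfg.n_soft, cfg.n_states, rate_soft,
            np.random.default_rng(s_soft),
        )
    if cfg.missing_hard > 0:
        cols_hard = mask_missing(
            cols_hard, cfg.missing_hard, np.random.default_rng(s_mask_h)
        )
    if cfg.missing_soft > 0:
        cols_soft = mask_missing(
            cols_soft, cfg.missing_soft, np.random.default_rng(s_mask_s)
        )
    taxa = sorted(tree_hard.leaf_labels)
    matrix = CharacterMatrix(
        taxa=tuple(taxa),
        columns=tuple(cols_hard + cols_soft),
        ordering=(UNORDERED,) * (cfg.n_hard + cfg.n_soft),
        partition=(HARD,) * cfg.n_hard + (SOFT,) * cfg.n_soft,
        dataset_id=f"sim{cfg.seed}",
        clade="",
    )
    return SimulatedDataset(
        matrix=matrix,
        tree_hard=tree_hard,
        tree_soft=tree_soft,
        reference=reference,
        config=cfg,
    )
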