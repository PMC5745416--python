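"""Maximum-parsimony character scoring and retention indices.

Characters are scored on a fixed topology by dynamic programming over
node state assignments (Sankoff).  Two step costs are supported:

* ``unordered`` — any state change costs 1 (Fitch counting);
* ``ordered`` — changing between integer states ``i`` and ``j`` costs
  ``|i - j|`` (linear / Wagner ordering).

Missing cells contribute no constraint (they may take any state at zero
cost).  Polymorphic cells use union semantics: the cell may be resolved
to any member of its state set.  Polytomies are scored as hard
polytomies — the DP runs on the multifurcating topology as given.

The retention index of a character with observed steps ``s``, minimum
conceivable steps ``m`` (over all trees) and maximum conceivable steps
``g`` (the star-tree length) is ``ri = (g - s) / (g - m)``: 1 means no
homoplasy on the tree, 0 means the tree explains the character no better
than a star.  The ensemble index of a partition is
``RI = (sum g - sum s) / (sum g - sum m)`` over its parsimony-informative
characters (those with ``g > m``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .characters import (
    MISSING,
    ORDERED,
    UNORDERED,
    CharacterColumn,
    CharacterMatrix,
)
from .errors import (
    DegeneratePartitionError,
    TreeMismatchError,
    UninformativeCharacterError,
    ValidationError,
)
from .trees import PhyloTree

_BIG = np.int64(1) << 40


# ---------------------------------------------------------------------------
# scoring on a fixed tree
# ---------------------------------------------------------------------------

def _leaf_cost_table(columns, orderings, taxa, K):
    """Per-taxon leaf cost vectors, shape (n_taxa, C, K)."""
    n = len(taxa)
    C = len(columns)
    costs = np.full((n, C, K), _BIG, dtype=np.int64)
    for c, col in enumerate(columns):
        for i, cellv in enumerate(col.cells):
            if cellv is MISSING:
                costs[i, c, :] = 0
            else:
                for s in cellv:
                    costs[i, c, s] = 0
    return costs


def subset_lengths(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Parsimony steps of each character in ``subset`` on ``tree``.

    Vectorized over characters; exact for multifurcating trees and for
    both ordering types.  Returns an int array aligned with ``subset``.
    """
    if subset is None:
        subset = range(matrix.n_characters)
    subset = list(subset)
    columns = [matrix.columns[j] for j in subset]
    orderings = [matrix.ordering[j] for j in subset]
    if not columns:
        return np.zeros(0, dtype=np.int64)

    leaf_set = set(tree.leaf_labels)
    absent = [t for t in matrix.taxa if t not in leaf_set]
    if absent:
        raise TreeMismatchError(
            f"matrix taxa missing from tree: {absent[:5]}"
        )

    max_state = 0
    for col in columns:
        if col.observed_states:
            max_state = max(max_state, col.observed_states[-1])
    K = max_state + 1
    C = len(columns)

    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    leaf_costs = _leaf_cost_table(columns, orderings, matrix.taxa, K)

    states = np.arange(K)
    cost_un = np.ones((K, K), dtype=np.int64) - np.eye(K, dtype=np.int64)
    cost_od = np.abs(states[:, None] - states[None, :]).astype(np.int64)
    un = np.array([o == UNORDERED for o in orderings])
    od = ~un

    cost_of = {}  # id(node) -> (C, K) array
    root = tree.dendropy_tree.seed_node
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            if lab in taxon_index:
                cost_of[id(nd)] = leaf_costs[taxon_index[lab]]
            else:
                # leaf present in the tree but absent from the matrix:
                # unconstrained, contributes nothing
                cost_of[id(nd)] = np.zeros((C, K), dtype=np.int64)
            continue
        total = np.zeros((C, K), dtype=np.int64)
        for ch in nd.child_nodes():
            cc = cost_of.pop(id(ch))
            contrib = np.empty((C, K), dtype=np.int64)
            if un.any():
                contrib[un] = (cc[un, None, :] + cost_un[None]).min(axis=2)
            if od.any():
                contrib[od] = (cc[od, None, :] + cost_od[None]).min(axis=2)
            total += contrib
        cost_of[id(nd)] = total
    return cost_of[id(root)].min(axis=1)


def character_length(
    tree: PhyloTree,
    taxa: Sequence[str],
    column: CharacterColumn,
    ordering: str = UNORDERED,
) -> int:
    """Minimum number of state changes the tree requires for one character."""
    mat = CharacterMatrix(
        tuple(taxa), (column,), (ordering,), ("hard",)
    )
    return int(subset_lengths(tree, mat, [0])[0])


def tree_length(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    subset: Sequence[int] | None = None,
) -> int:
    """Summed parsimony steps of the characters in ``subset``."""
    return int(subset_lengths(tree, matrix, subset).sum())


# ---------------------------------------------------------------------------
# tree-free step bounds
# ---------------------------------------------------------------------------

def _live_cells(column: CharacterColumn):
    cells = [c for c in column.cells if c is not MISSING]
    if not cells:
        raise UninformativeCharacterError(
            "column is entirely missing; steps are undefined"
        )
    return cells


def min_steps(column: CharacterColumn, ordering: str = UNORDERED) -> int:
    """Minimum conceivable steps ``m`` over all trees.

    Unordered: one less than the size of the smallest state set hitting
    every cell (with no polymorphism this is #distinct states - 1).
    Ordered: the smallest achievable state span over resolutions of the
    polymorphic cells.
    """
    cells = _live_cells(column)
    if ordering == ORDERED:
        union = sorted(set().union(*cells))
        best = None
        for a in union:
            # a is the minimum resolved state; each cell picks its
            # smallest member >= a
            hi = a
            ok = True
            for cl in cells:
                cand = [x for x in cl if x >= a]
                if not cand:
                    ok = False
                    break
                hi = max(hi, min(cand))
            if ok:
                span = hi - a
                best = span if best is None else min(best, span)
        return int(best)
    # unordered: smallest hitting set of the cell state sets
    alphabet = sorted(set().union(*cells))
    if all(len(cl) == 1 for cl in cells):
        return len(alphabet) - 1
    for r in range(1, len(alphabet) + 1):
        for combo in combinations(alphabet, r):
            s = set(combo)
            if all(s & cl for cl in cells):
                return r - 1
    raise AssertionError("unreachable: full alphabet always hits")


def max_steps(column: CharacterColumn, ordering: str = UNORDERED) -> int:
    """Maximum conceivable steps ``g``: the star-tree parsimony length."""
    cells = _live_cells(column)
    if ordering == ORDERED:
        lo = min(min(cl) for cl in cells)
        hi = max(max(cl) for cl in cells)
        return int(
            min(
                sum(min(abs(x - a) for x in cl) for cl in cells)
                for a in range(lo, hi + 1)
            )
        )
    alphabet = set().union(*cells)
    best_count = max(
        sum(1 for cl in cells if s in cl) for s in alphabet
    )
    return len(cells) - best_count


def retention_index(s: int, m: int, g: int) -> float:
    """``(g - s) / (g - m)``; defined only for informative characters."""
    if not (m <= s <= g):
        raise ValidationError(f"require m <= s <= g, got s={s}, m={m}, g={g}")
    if g == m:
        raise UninformativeCharacterError(
            "retention index undefined when g == m (uninformative character)"
        )
    return (g - s) / (g - m)


def is_informative(column: CharacterColumn, ordering: str = UNORDERED) -> bool:
    """True when the character can discriminate among trees (g > m)."""
    try:
        return max_steps(column, ordering) > min_steps(column, ordering)
    except UninformativeCharacterError:
        return False


def informative_indices(
    matrix: CharacterMatrix, subset: Sequence[int] | None = None
) -> tuple:
    """Indices (within the matrix) of parsimony-informative characters."""
    if subset is None:
        subset = range(matrix.n_characters)
    return tuple(
        j
        for j in subset
        if is_informative(matrix.columns[j], matrix.ordering[j])
    )


# ---------------------------------------------------------------------------
# per-character and ensemble fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterFit:
    """Fit of one character on a tree: steps and retention index."""

    index: int
    s: int
    m: int
    g: int
    ri: float


@dataclass(frozen=True)
class PartitionFit:
    """Per-character fits plus the ensemble retention index of a partition."""

    fits: tuple
    RI: float


def partition_fit(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    subset: Sequence[int] | None = None,
) -> PartitionFit:
    """Fit the informative characters of ``subset`` on ``tree``.

    Uninformative characters (g == m after any taxon pruning already
    applied to ``matrix``) are excluded; an empty informative subset is
    an error because the ensemble RI would be 0/0.
    """
    if subset is None:
        subset = range(matrix.n_characters)
    keep = informative_indices(matrix, subset)
    if not keep:
        raise DegeneratePartitionError(
            "no parsimony-informative characters in subset"
        )
    steps = subset_lengths(tree, matrix, keep)
    fits = []
    for j, s in zip(keep, steps):
        m = min_steps(matrix.columns[j], matrix.ordering[j])
        g = max_steps(matrix.columns[j], matrix.ordering[j])
        fits.append(CharacterFit(j, int(s), m, g, retention_index(int(s), m, g)))
    sum_s = sum(f.s for f in fits)
    sum_m = sum(f.m for f in fits)
    sum_g = sum(f.g for f in fits)
    return PartitionFit(tuple(fits), (sum_g - sum_s) / (sum_g - sum_m))
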