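"""Robinson–Foulds distances and the nearest-neighbour set statistic.

The RF distance between two trees on the same leaf set is the number of
nontrivial bipartitions present in exactly one of them (symmetric
difference).  For sets of trees, the incongruence statistic used by the
IRD test is the mean over every tree of its distance to the nearest
tree in the other set, pooled over both directions by default.
"""

from __future__ import annotations

from typing import Sequence

from .errors import TreeMismatchError, ValidationError
from .search import TreeSet
from .trees import PhyloTree


def rf_distance(tree1: PhyloTree, tree2: PhyloTree) -> int:
    """Symmetric-difference (Robinson–Foulds) distance.

    Requires identical leaf sets; polytomous trees simply contribute the
    splits they have.  The maximum between two binary trees on n leaves
    is ``2(n - 3)``.
    """
    if set(tree1.leaf_labels) != set(tree2.leaf_labels):
        raise TreeMismatchError("trees have different leaf sets")
    order = sorted(tree1.leaf_labels)
    a = tree1.bipartition_masks(order)
    b = tree2.bipartition_masks(order)
    return len(a ^ b)


def rf_from_splits(splits_a: frozenset, splits_b: frozenset) -> int:
    """RF distance from two canonical split sets over one taxon order."""
    return len(splits_a ^ splits_b)


def nn_mean_distance(
    set_a: TreeSet | Sequence[PhyloTree],
    set_b: TreeSet | Sequence[PhyloTree],
    direction: str = "both",
) -> float:
    """Mean nearest-neighbour RF distance between two tree sets.

    With ``direction="both"`` (default) the nearest-neighbour distances
    of all trees in A (to B) and all trees in B (to A) are pooled before
    averaging, giving a symmetric statistic; ``"a_to_b"`` averages only
    the A-side values.
    """
    if direction not in ("both", "a_to_b"):
        raise ValidationError("direction must be 'both' or 'a_to_b'")
    if isinstance(set_a, TreeSet) != isinstance(set_b, TreeSet):
        # mixed inputs: fall back to PhyloTree form so split masks share
        # one taxon order
        set_a = set_a.trees if isinstance(set_a, TreeSet) else set_a
        set_b = set_b.trees if isinstance(set_b, TreeSet) else set_b
    elif isinstance(set_a, TreeSet) and set_a.taxa != set_b.taxa:
        raise TreeMismatchError("tree sets are indexed by different taxa")
    sa = _split_sets(set_a)
    sb = _split_sets(set_b)
    if not sa or not sb:
        raise ValidationError("nn_mean_distance needs two non-empty tree sets")
    d = [[rf_from_splits(x, y) for y in sb] for x in sa]
    a_side = [min(row) for row in d]
    if direction == "a_to_b":
        return sum(a_side) / len(a_side)
    b_side = [min(d[i][j] for i in range(len(sa))) for j in range(len(sb))]
    pooled = a_side + b_side
    return sum(pooled) / len(pooled)


def _split_sets(trees) -> list:
    if isinstance(trees, TreeSet):
        return list(trees.splits)
    trees = list(trees)
    if not trees:
        return []
    order = sorted(trees[0].leaf_labels)
    leafset = set(trees[0].leaf_labels)
    for t in trees[1:]:
        if set(t.leaf_labels) != leafset:
            raise TreeMismatchError("trees in a set must share one leaf set")
    return [t.bipartition_masks(order) for t in trees]
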