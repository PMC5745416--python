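"""Homoplasy of hard vs soft characters on an independent reference tree.

Morphological characters are optimized (by parsimony) onto a molecular
tree taken as an external benchmark.  Retention indices then measure
homoplasy relative to that benchmark; because the comparison is made
*within* a dataset, the numbers of taxa and characters cancel out and
the hard/soft contrast directly tests whether homoplasy is concentrated
in one partition.

Taxa absent from the reference tree are excluded before anything else
is computed (minimum/maximum steps are recomputed on the pruned taxon
set), and characters that are invariant or autapomorphic on the pruned
set are omitted.  A dataset needs at least 10 shared taxa by default,
mirroring the usual molecular-coverage inclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .characters import CharacterMatrix
from .errors import CoverageError, DegeneratePartitionError, ValidationError
from .parsimony import informative_indices, partition_fit
from .trees import PhyloTree


@dataclass(frozen=True)
class ConsistencyResult:
    """Hard/soft retention indices on a reference tree plus the MWW test."""

    ri_hard: tuple
    ri_soft: tuple
    RI_hard: float
    RI_soft: float
    mww_p: float
    n_taxa_used: int
    n_excluded_taxa: int
    n_excluded_characters: int


def prune_to_reference(
    matrix: CharacterMatrix,
    reference: PhyloTree,
    min_shared: int = 10,
):
    """Restrict matrix and reference tree to their shared taxa.

    Raises :class:`CoverageError` when fewer than ``min_shared`` taxa are
    shared (set ``min_shared=4`` to relax the inclusion rule).
    """
    ref_leaves = set(reference.leaf_labels)
    shared = [t for t in matrix.taxa if t in ref_leaves]
    if len(shared) < min_shared:
        raise CoverageError(
            f"only {len(shared)} taxa shared with the reference tree "
            f"(minimum {min_shared})"
        )
    pruned_matrix = (
        matrix if len(shared) == matrix.n_taxa else matrix.take_taxa(shared)
    )
    pruned_tree = (
        reference
        if len(shared) == reference.n_leaves
        else reference.prune_to(shared)
    )
    return pruned_matrix, pruned_tree


def filter_informative(matrix: CharacterMatrix) -> tuple:
    """Indices of characters informative on the (already pruned) taxon set."""
    keep = informative_indices(matrix)
    if not keep:
        raise DegeneratePartitionError("no informative characters remain")
    return keep


def mww_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum p-value.

    Exact by enumeration when the pooled size is <= 20 with no ties;
    otherwise the normal approximation with tie and continuity
    corrections.  An all-tied input carries no rank information and
    returns 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("MWW needs two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def consistency_test(
    matrix: CharacterMatrix,
    reference: PhyloTree,
    min_shared: int = 10,
) -> ConsistencyResult:
    """Compare hard and soft homoplasy on a reference tree.

    Per-character retention indices are computed on the pruned reference
    topology for each partition; the ensemble RI uses summed step terms
    over the informative characters only; the two ri samples are
    compared with a two-sided MWW test.
    """
    pm, pt = prune_to_reference(matrix, reference, min_shared=min_shared)
    hard = pm.hard_indices
    soft = pm.soft_indices
    if not hard or not soft:
        raise DegeneratePartitionError("both partitions must be non-empty")
    try:
        fit_hard = partition_fit(pt, pm, hard)
    except DegeneratePartitionError:
        raise DegeneratePartitionError(
            "hard partition uninformative on the shared taxon set"
        ) from None
    try:
        fit_soft = partition_fit(pt, pm, soft)
    except DegeneratePartitionError:
        raise DegeneratePartitionError(
            "soft partition uninformative on the shared taxon set"
        ) from None
    ri_hard = tuple(f.ri for f in fit_hard.fits)
    ri_soft = tuple(f.ri for f in fit_soft.fits)
    return ConsistencyResult(
        ri_hard=ri_hard,
        ri_soft=ri_soft,
        RI_hard=fit_hard.RI,
        RI_soft=fit_soft.RI,
        mww_p=mww_test(ri_hard, ri_soft),
        n_taxa_used=pm.n_taxa,
        n_excluded_taxa=matrix.n_taxa - pm.n_taxa,
        n_excluded_characters=(
            pm.n_characters - len(ri_hard) - len(ri_soft)
        ),
    )
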