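"""ILD and IRD permutation tests of hard-vs-soft partition homogeneity.

Both tests compare the observed two-partition statistic against a null
distribution obtained by randomly reassigning the pooled characters to
two partitions of the original sizes (sampling without replacement):

* **ILD** (incongruence length difference): statistic = MPT length of
  the hard partition + MPT length of the soft partition.  Incongruent
  partitions can each be explained on their own tree with fewer steps
  than random partitions of the same characters, so the test is
  one-tailed *lower*.
* **IRD** (incongruence relationship difference): statistic = mean
  nearest-neighbour Robinson–Foulds distance between the two partitions'
  sets of most parsimonious trees; one-tailed *upper*.

P-values use the add-one rule ``(b + 1) / (R + 1)`` where ``b`` counts
null replicates at or beyond the observed value, guaranteeing valid
(never zero) permutation p-values.  By default parsimony-uninformative
characters are excluded from the pool before repartitioning (the
classic ILD recommendation); a switch retains them for sensitivity
checks.  Everything is deterministic given the master seed: each
replicate draws from an independent substream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .characters import CharacterMatrix
from .errors import ConfigError, DegeneratePartitionError, ValidationError
from .parsimony import informative_indices, min_steps
from .search import SearchConfig, parsimony_search
from .treedist import nn_mean_distance

LOWER = "lower"
UPPER = "upper"


@dataclass(frozen=True)
class PermutationTestResult:
    """Outcome of one permutation test."""

    test: str
    observed: float
    null_values: tuple
    replicates: int
    p_value: float
    tail: str
    seed: int

    def __post_init__(self):
        if len(self.null_values) != self.replicates:
            raise ValidationError(
                "null replicate count must equal the requested replicates"
            )


def _permutation_p(observed, null_values, tail):
    if tail == LOWER:
        b = sum(1 for v in null_values if v <= observed)
    else:
        b = sum(1 for v in null_values if v >= observed)
    return (b + 1) / (len(null_values) + 1)


def _pool(matrix: CharacterMatrix, informative_only: bool):
    hard = matrix.hard_indices
    soft = matrix.soft_indices
    inf_hard = informative_indices(matrix, hard)
    inf_soft = informative_indices(matrix, soft)
    if not inf_hard:
        raise DegeneratePartitionError(
            "hard partition has no parsimony-informative characters"
        )
    if not inf_soft:
        raise DegeneratePartitionError(
            "soft partition has no parsimony-informative characters"
        )
    if informative_only:
        return list(inf_hard), list(inf_soft)
    return list(hard), list(soft)


def _fixed_length(matrix, subset):
    """MPT length of a subset with no informative characters.

    Every character with g == m attains its minimum on every tree, so
    the subset's optimal length is the same on all trees.
    """
    total = 0
    for j in subset:
        try:
            total += min_steps(matrix.columns[j], matrix.ordering[j])
        except Exception:
            pass  # all-missing column scores 0 on any tree
    return total


def _side(matrix, subset, cfg, want_trees):
    """(length, tree set or None) for one partition of one repartition."""
    if not informative_indices(matrix, subset):
        return _fixed_length(matrix, subset), None
    ts = parsimony_search(
        matrix, subset, config=cfg, collect_trees=want_trees
    )
    return ts.score, ts


def partition_homogeneity_tests(
    matrix: CharacterMatrix,
    reps: int = 999,
    search: SearchConfig | None = None,
    seed: int = 0,
    informative_only: bool = True,
    direction: str = "both",
    which: str = "both",
):
    """Run the ILD and/or IRD test off one set of shared searches.

    Returns ``(ild_result, ird_result)``; the member not requested by
    ``which`` in {'ild', 'ird', 'both'} is ``None``.  Sharing the
    repartitions and searches between the two statistics halves the cost
    of running both and leaves each test's permutation null unchanged.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if which not in ("ild", "ird", "both"):
        raise ConfigError("which must be 'ild', 'ird' or 'both'")
    if matrix.n_taxa < 4:
        raise ValidationError("partition tests need at least 4 taxa")
    base = search or SearchConfig()
    want_trees = which in ("ird", "both")

    pool_hard, pool_soft = _pool(matrix, informative_only)
    pooled = pool_hard + pool_soft
    n_hard = len(pool_hard)

    master = np.random.SeedSequence(seed)
    streams = master.spawn(reps + 1)

    def _stat(idx_h, idx_s, stream):
        s_h, s_s = stream.spawn(2)
        len_h, ts_h = _side(
            matrix, idx_h, base.with_seed(_small(s_h)), want_trees
        )
        len_s, ts_s = _side(
            matrix, idx_s, base.with_seed(_small(s_s)), want_trees
        )
        ild_stat = len_h + len_s
        ird_stat = None
        if want_trees:
            if ts_h is None or ts_s is None:
                # a side with no informative characters is optimal on
                # every topology: its nearest neighbour is always exact
                ird_stat = 0.0
            else:
                ird_stat = nn_mean_distance(ts_h, ts_s, direction=direction)
        return ild_stat, ird_stat

    obs_ild, obs_ird = _stat(pool_hard, pool_soft, streams[0])

    null_ild = []
    null_ird = []
    for r in range(1, reps + 1):
        sub = streams[r].spawn(2)
        rng = np.random.default_rng(sub[0])
        perm = rng.permutation(len(pooled))
        idx_h = [pooled[i] for i in perm[:n_hard]]
        idx_s = [pooled[i] for i in perm[n_hard:]]
        v_ild, v_ird = _stat(idx_h, idx_s, sub[1])
        null_ild.append(v_ild)
        null_ird.append(v_ird)

    ild = ird = None
    if which in ("ild", "both"):
        ild = PermutationTestResult(
            test="ILD",
            observed=float(obs_ild),
            null_values=tuple(float(v) for v in null_ild),
            replicates=reps,
            p_value=_permutation_p(obs_ild, null_ild, LOWER),
            tail=LOWER,
            seed=seed,
        )
    if which in ("ird", "both"):
        ird = PermutationTestResult(
            test="IRD",
            observed=float(obs_ird),
            null_values=tuple(float(v) for v in null_ird),
            replicates=reps,
            p_value=_permutation_p(obs_ird, null_ird, UPPER),
            tail=UPPER,
            seed=seed,
        )
    return ild, ird


def _small(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def ild_test(
    matrix: CharacterMatrix,
    reps: int = 999,
    search: SearchConfig | None = None,
    seed: int = 0,
    informative_only: bool = True,
) -> PermutationTestResult:
    """Incongruence length difference test (one-tailed lower)."""
    ild, _ = partition_homogeneity_tests(
        matrix, reps=reps, search=search, seed=seed,
        informative_only=informative_only, which="ild",
    )
    return ild


def ird_test(
    matrix: CharacterMatrix,
    reps: int = 999,
    search: SearchConfig | None = None,
    seed: int = 0,
    informative_only: bool = True,
    direction: str = "both",
) -> PermutationTestResult:
    """Incongruence relationship difference test (one-tailed upper)."""
    _, ird = partition_homogeneity_tests(
        matrix, reps=reps, search=search, seed=seed,
        informative_only=informative_only, direction=direction, which="ird",
    )
    return ird
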