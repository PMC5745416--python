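"""Heuristic and exhaustive maximum-parsimony tree search.

The heuristic follows the classic recipe: stepwise random-addition
starting trees, steepest-descent hill climbing under a configurable
rearrangement neighbourhood (NNI, SPR or TBR), and a final plateau walk
that collects every distinct topology tied at the best length found, up
to a store cap.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _arrays as A
from ._kernels import BIG, fitch_score, sankoff_linear_score
from .characters import MISSING, ORDERED, UNORDERED, CharacterMatrix
from .errors import ConfigError, DegeneratePartitionError, ValidationError
from .parsimony import informative_indices
from .trees import PhyloTree

REARRANGEMENTS = ("nni", "spr", "tbr")


@dataclass(frozen=True)
class SearchConfig:
    """Heuristic search settings.

    ``n_starts`` random-addition replicates, hill climbing by
    ``rearrangement`` moves, retaining at most ``max_trees`` tied optima.
    """

    n_starts: int = 10
    rearrangement: str = "spr"
    max_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")
        if self.max_trees < 1:
            raise ConfigError("max_trees must be >= 1")
        if self.rearrangement not in REARRANGEMENTS:
            raise ConfigError(
                f"rearrangement must be one of {REARRANGEMENTS}"
            )

    def with_seed(self, seed: int) -> "SearchConfig":
        return replace(self, seed=int(seed))


class TreeSet:
    """A set of distinct equally parsimonious unrooted topologies."""

    def __init__(self, taxa, score, splits, arrays, capped):
        self.taxa = tuple(taxa)
        self.score = int(score)
        self.capped = bool(capped)
        self._splits = tuple(splits)
        self._arrays = tuple(arrays)
        self._trees = None

    def __len__(self):
        return len(self._splits)

    @property
    def splits(self) -> tuple:
        """Canonical bipartition-mask sets, one frozenset per tree.

        Masks index into ``self.taxa`` (the matrix taxon order).
        """
        return self._splits

    @property
    def trees(self) -> tuple:
        """The topologies as :class:`PhyloTree` objects (built lazily)."""
        if self._trees is None:
            self._trees = tuple(
                A.phylo_from_arrays(lf, rg, rt, self.taxa)
                for (lf, rg, rt) in self._arrays
            )
        return self._trees

    def __repr__(self):
        cap = ", capped" if self.capped else ""
        return f"TreeSet({len(self)} trees, score {self.score}{cap})"


class _ScoreContext:
    """Kernel inputs for scoring one character subset on array trees."""

    def __init__(self, matrix: CharacterMatrix, subset):
        self.n = matrix.n_taxa
        self.M = 2 * self.n - 1
        self.root = self.M - 1
        un = [j for j in subset if matrix.ordering[j] == UNORDERED]
        od = [j for j in subset if matrix.ordering[j] == ORDERED]
        n, M = self.n, self.M

        self.masks = np.zeros((M, len(un)), dtype=np.int64)
        for c, j in enumerate(un):
            col = matrix.columns[j]
            colmask = 0
            for st in col.observed_states:
                colmask |= 1 << st
            if colmask == 0:
                colmask = 1  # entirely-missing column, scores 0 anywhere
            for i, cellv in enumerate(col.cells):
                if cellv is MISSING:
                    self.masks[i, c] = colmask
                else:
                    m = 0
                    for st in cellv:
                        m |= 1 << st
                    self.masks[i, c] = m

        K = 1
        for j in od:
            st = matrix.columns[j].observed_states
            if st:
                K = max(K, st[-1] + 1)
        self.costs = np.zeros((M, len(od), K), dtype=np.int64)
        for c, j in enumerate(od):
            col = matrix.columns[j]
            for i, cellv in enumerate(col.cells):
                if cellv is MISSING:
                    self.costs[i, c, :] = 0
                else:
                    self.costs[i, c, :] = BIG
                    for st in cellv:
                        self.costs[i, c, st] = 0

        self._order = np.zeros(M, dtype=np.int64)
        self._stack = np.zeros(M, dtype=np.int64)
        self.has_un = self.masks.shape[1] > 0
        self.has_od = self.costs.shape[1] > 0

    def score(self, left, right) -> int:
        total = 0
        if self.has_un:
            total += int(
                fitch_score(self.root, left, right, self.masks,
                            self._order, self._stack)
            )
        if self.has_od:
            total += int(
                sankoff_linear_score(self.root, left, right, self.costs,
                                     self._order, self._stack)
            )
        return total


def _snapshot(par, left, right):
    return par.copy(), left.copy(), right.copy()


def _random_addition(ctx, rng):
    n = ctx.n
    perm = [int(v) for v in rng.permutation(n)]
    par, left, right = A.blank_arrays(n)
    t0 = perm[0]
    A.init_triplet(par, left, right, t0, perm[1], perm[2], n)
    used = [perm[1], perm[2], n]  # attachment candidates; root leaf excluded
    next_internal = n + 1
    score = ctx.score(left, right)
    for k in range(3, n):
        z = perm[k]
        best = None
        best_xs = []
        for x in used:
            A.insert_leaf(par, left, right, x, z, next_internal)
            s = ctx.score(left, right)
            A.uninsert_leaf(par, left, right, x, next_internal)
            if best is None or s < best:
                best, best_xs = s, [x]
            elif s == best:
                best_xs.append(x)
        x = best_xs[int(rng.integers(len(best_xs)))]
        A.insert_leaf(par, left, right, x, z, next_internal)
        used.append(z)
        used.append(next_internal)
        next_internal += 1
        score = best
    return (par, left, right), score


def _nni_neighbors(ctx, par, left, right):
    """Yield (score, snapshot) for every NNI neighbour; tree restored."""
    root = ctx.root
    for v in range(ctx.n, ctx.M - 1):
        p = par[v]
        if p == root:
            continue
        sib = left[p] if right[p] == v else right[p]
        sib_slot_left = left[p] == sib
        for take_left in (True, False):
            b = left[v] if take_left else right[v]
            # exchange sib <-> b across edge (p, v)
            if sib_slot_left:
                left[p] = b
            else:
                right[p] = b
            if take_left:
                left[v] = sib
            else:
                right[v] = sib
            par[b] = p
            par[sib] = v
            yield ctx.score(left, right), _snapshot(par, left, right)
            if sib_slot_left:
                left[p] = sib
            else:
                right[p] = sib
            if take_left:
                left[v] = b
            else:
                right[v] = b
            par[b] = v
            par[sib] = p


def _spr_neighbors(ctx, par, left, right):
    """Yield (score, snapshot) for SPR neighbours; tree restored.

    Moves pruning the root-leaf pendant subtree are not generated (the
    rooted representation hangs from that leaf); random-addition restarts
    compensate for the slightly reduced neighbourhood.
    """
    root = ctx.root
    for v in range(ctx.M):
        if v == root:
            continue
        p = par[v]
        if p == root or p < 0:
            continue
        g = par[p]
        s = left[p] if right[p] == v else right[p]
        s_slot_left = left[p] == s
        # prune: replace p by s under g
        if left[g] == p:
            g_slot_left = True
            left[g] = s
        else:
            g_slot_left = False
            right[g] = s
        par[s] = g
        # nodes inside the pruned subtree
        inside = set()
        stk = [v]
        while stk:
            u = stk.pop()
            inside.add(u)
            if left[u] >= 0:
                stk.append(left[u])
                stk.append(right[u])
        for x in range(ctx.M):
            if (
                x == root
                or par[x] < 0
                or x in inside
                or x == s  # regraft in place: identity
                or x == p
            ):
                continue
            q = par[x]
            x_slot_left = left[q] == x
            if x_slot_left:
                left[q] = p
            else:
                right[q] = p
            par[p] = q
            if s_slot_left:
                left[p] = x
            else:
                right[p] = x
            par[x] = p
            yield ctx.score(left, right), _snapshot(par, left, right)
            if x_slot_left:
                left[q] = x
            else:
                right[q] = x
            par[x] = q
        # restore p's child slot and reattach above s
        if s_slot_left:
            left[p] = s
        else:
            right[p] = s
        if g_slot_left:
            left[g] = p
        else:
            right[g] = p
        par[p] = g
        par[s] = p


def _component(adj, start, blocked):
    """Nodes reachable from ``start`` without crossing edge (start, blocked)."""
    out = {start}
    stk = [start]
    while stk:
        v = stk.pop()
        for u in adj[v]:
            if v == start and u == blocked:
                continue
            if u not in out:
                out.add(u)
                stk.append(u)
    return out


def _half_after_cut(adj, comp, cut_end):
    """Adjacency of one bisection half, degree-2 cut endpoint suppressed."""
    sub = {v: {u for u in adj[v] if u in comp} for v in comp}
    if cut_end in sub and len(sub[cut_end]) == 2:
        a, b = sorted(sub[cut_end])
        sub[a].discard(cut_end)
        sub[b].discard(cut_end)
        sub[a].add(b)
        sub[b].add(a)
        del sub[cut_end]
    return sub


def _attachment_edges(sub):
    """Reconnection points: edges of the half, or the lone node itself."""
    if len(sub) == 1:
        (node,) = sub
        return [(node,)]
    return sorted(
        {(min(u, w), max(u, w)) for u in sub for w in sub[u]}
    )


def _tbr_neighbors(ctx, par, left, right):
    """Yield (score, snapshot) for TBR neighbours (generic slow path).

    Every edge of the unrooted tree is bisected and every pair of
    reconnection edges in the two halves is rejoined.  SPR and NNI moves
    arise as special cases; duplicates are deduplicated downstream by
    topology key.
    """
    n = ctx.n
    adj = A.arrays_to_adjacency(par, left, right, ctx.root)
    edges = sorted({(min(u, w), max(u, w)) for u in adj for w in adj[u]})
    fresh0 = max(adj) + 1
    for (u, w) in edges:
        comp_u = _component(adj, u, w)
        comp_w = _component(adj, w, u)
        sub_u = _half_after_cut(adj, comp_u, u)
        sub_w = _half_after_cut(adj, comp_w, w)
        for e1 in _attachment_edges(sub_u):
            for e2 in _attachment_edges(sub_w):
                new = {v: set(ns) for v, ns in sub_u.items()}
                for v, ns in sub_w.items():
                    new[v] = set(ns)
                fresh = fresh0

                def attach(edge):
                    nonlocal fresh
                    if len(edge) == 1:
                        return edge[0]
                    a, b = edge
                    mid = fresh
                    fresh += 1
                    new[a].discard(b)
                    new[b].discard(a)
                    new[mid] = {a, b}
                    new[a].add(mid)
                    new[b].add(mid)
                    return mid

                m1 = attach(e1)
                m2 = attach(e2)
                new[m1].add(m2)
                new[m2].add(m1)
                try:
                    np_, nl, nr, _ = A.adjacency_to_arrays(new, n)
                except (ValidationError, KeyError):
                    continue
                yield ctx.score(nl, nr), (np_, nl, nr)


def _neighbor_scores(ctx, par, left, right, rearrangement):
    if rearrangement == "nni":
        yield from _nni_neighbors(ctx, par, left, right)
    elif rearrangement == "spr":
        yield from _spr_neighbors(ctx, par, left, right)
    else:
        yield from _tbr_neighbors(ctx, par, left, right)


def _hill_climb(ctx, arrs, score, rearrangement):
    par, left, right = arrs
    while True:
        best = score
        best_snap = None
        for s, snap in _neighbor_scores(ctx, par, left, right, rearrangement):
            if s < best:
                best = s
                best_snap = snap
        if best_snap is None:
            return (par, left, right), score
        par, left, right = best_snap
        score = best


def _plateau(ctx, pool, best_score, cfg):
    """Collect every topology tied at best_score reachable through ties."""
    capped = False
    queue = list(pool.values())
    i = 0
    while i < len(queue):
        par, left, right = queue[i]
        i += 1
        for s, snap in _neighbor_scores(
            ctx, par.copy(), left.copy(), right.copy(), cfg.rearrangement
        ):
            if s < best_score:
                # a tie-walk revealed a better region: restart there
                snap2, s2 = _hill_climb(ctx, snap, s, cfg.rearrangement)
                best_score = s2
                key = A.splits_key(*snap2, ctx.root, ctx.n)
                pool = {key: snap2}
                queue = [snap2]
                i = 0
                break
            if s == best_score and len(pool) < cfg.max_trees:
                key = A.splits_key(snap[0], snap[1], snap[2], ctx.root, ctx.n)
                if key not in pool:
                    pool[key] = snap
                    queue.append(snap)
            elif s == best_score:
                key = A.splits_key(snap[0], snap[1], snap[2], ctx.root, ctx.n)
                if key not in pool:
                    capped = True
    return best_score, pool, capped


def parsimony_search(
    matrix: CharacterMatrix,
    subset: Sequence[int] | None = None,
    config: SearchConfig | None = None,
    collect_trees: bool = True,
) -> TreeSet:
    """Heuristic search for the most parsimonious trees of a subset.

    Returns a :class:`TreeSet` of distinct topologies tied at the best
    length found.  With ``collect_trees=False`` the plateau walk is
    skipped and only the trees found at the ends of the hill climbs are
    kept — sufficient when only the score is needed (e.g. the ILD
    statistic).
    """
    cfg = config or SearchConfig()
    if subset is None:
        subset = tuple(range(matrix.n_characters))
    subset = tuple(subset)
    if matrix.n_taxa < 4:
        raise ValidationError(
            "parsimony search needs at least 4 taxa (trivial instance)"
        )
    if not informative_indices(matrix, subset):
        raise DegeneratePartitionError(
            "no parsimony-informative characters in subset"
        )
    ctx = _ScoreContext(matrix, subset)
    rng = np.random.default_rng(cfg.seed)
    best_score = None
    pool = {}
    for _ in range(cfg.n_starts):
        arrs, score = _random_addition(ctx, rng)
        arrs, score = _hill_climb(ctx, arrs, score, cfg.rearrangement)
        key = A.splits_key(*arrs, ctx.root, ctx.n)
        if best_score is None or score < best_score:
            best_score = score
            pool = {key: arrs}
        elif score == best_score and key not in pool:
            if len(pool) < cfg.max_trees:
                pool[key] = arrs
    capped = False
    if collect_trees:
        best_score, pool, capped = _plateau(ctx, pool, best_score, cfg)
    arrays = [(lf, rg, ctx.root) for (_, lf, rg) in pool.values()]
    return TreeSet(matrix.taxa, best_score, tuple(pool.keys()), arrays, capped)


def exhaustive_search(
    matrix: CharacterMatrix,
    subset: Sequence[int] | None = None,
    max_trees: int = 1000,
) -> TreeSet:
    """Exact search by enumeration of all unrooted binary topologies.

    Guarded to <= 9 taxa (135,135 topologies); used as the ground truth
    for validating the heuristic at desk scale.
    """
    n = matrix.n_taxa
    if not (4 <= n <= 9):
        raise ValidationError("exhaustive search is guarded to 4..9 taxa")
    if subset is None:
        subset = tuple(range(matrix.n_characters))
    ctx = _ScoreContext(matrix, tuple(subset))
    best = None
    pool = {}
    capped = False
    for par, left, right, root in A.enumerate_arrays(n):
        s = ctx.score(left, right)
        if best is None or s < best:
            best = s
            pool = {
                A.splits_key(par, left, right, root, n): (
                    par.copy(), left.copy(), right.copy()
                )
            }
            capped = False
        elif s == best:
            if len(pool) < max_trees:
                pool[A.splits_key(par, left, right, root, n)] = (
                    par.copy(), left.copy(), right.copy()
                )
            else:
                capped = True
    arrays = [(lf, rg, ctx.root) for (_, lf, rg) in pool.values()]
    return TreeSet(matrix.taxa, best, tuple(pool.keys()), arrays, capped)


def enumerate_all_topologies(taxa: Sequence[str]):
    """Yield every unrooted binary topology on the given labels.

    Guarded to 4..9 leaves; the count is ``(2n - 5)!!``.
    """
    n = len(taxa)
    if not (4 <= n <= 9):
        raise ValidationError(
            f"topology enumeration is guarded to 4..9 leaves, got {n}"
        )
    labels = list(taxa)
    for par, left, right, root in A.enumerate_arrays(n):
        yield A.phylo_from_arrays(left, right, root, labels)
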