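"""Rooted-array tree representation used by the heuristic search.

An unrooted binary topology on ``n`` leaves is stored as parent / left /
right arrays over ``M = 2n - 1`` nodes: leaf node ids equal matrix taxon
rows ``0..n-1``, internal nodes are ``n..M-2``, and node ``M - 1`` is a
virtual root placed on the pendant edge of one "root leaf".  Leaves have
``left == right == -1``.  All surgeries (leaf insertion, NNI swaps, SPR
prune/regraft) are O(1) pointer updates on these arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .trees import PhyloTree


def blank_arrays(n: int):
    M = 2 * n - 1
    par = np.full(M, -1, dtype=np.int64)
    left = np.full(M, -1, dtype=np.int64)
    right = np.full(M, -1, dtype=np.int64)
    return par, left, right


def init_triplet(par, left, right, t0: int, t1: int, t2: int, n: int):
    """Initial 3-leaf tree rooted on the pendant edge of ``t0``."""
    root = par.shape[0] - 1
    w = n
    left[root] = t0
    right[root] = w
    par[t0] = root
    par[w] = root
    left[w] = t1
    right[w] = t2
    par[t1] = w
    par[t2] = w
    return root, w


def insert_leaf(par, left, right, x: int, z: int, w: int):
    """Insert leaf ``z`` on the edge above node ``x`` via new internal ``w``."""
    p = par[x]
    if left[p] == x:
        left[p] = w
    else:
        right[p] = w
    par[w] = p
    left[w] = x
    right[w] = z
    par[x] = w
    par[z] = w


def uninsert_leaf(par, left, right, x: int, w: int):
    """Undo :func:`insert_leaf` (``w`` must still be directly above ``x``)."""
    p = par[w]
    if left[p] == w:
        left[p] = x
    else:
        right[p] = x
    par[x] = p


def subtree_leaf_masks(left, right, root: int) -> np.ndarray:
    """Bitmask of leaves below every node (pure-python postorder)."""
    M = left.shape[0]
    out = np.zeros(M, dtype=np.int64)
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        if left[v] >= 0:
            order.append(v)
            stack.append(left[v])
            stack.append(right[v])
        else:
            out[v] = 1 << v
    for v in reversed(order):
        out[v] = out[left[v]] | out[right[v]]
    return out


def splits_key(par, left, right, root: int, n: int) -> frozenset:
    """Canonical nontrivial bipartition set of the unrooted topology.

    Masks are taken over leaf ids and flipped to the side not containing
    leaf 0, matching :meth:`PhyloTree.bipartition_masks` when the taxon
    order used there is the matrix taxon order.
    """
    masks = subtree_leaf_masks(left, right, root)
    full = (1 << n) - 1
    out = set()
    for v in range(left.shape[0]):
        if v == root or par[v] < 0:
            continue
        m = int(masks[v])
        if m & 1:
            m ^= full
        k = m.bit_count()
        if 2 <= k <= n - 2:
            out.add(m)
    return frozenset(out)


def arrays_to_newick(left, right, root: int, labels) -> str:
    def rec(v):
        if left[v] < 0:
            return labels[v]
        return f"({rec(left[v])},{rec(right[v])})"

    return f"({rec(left[root])},{rec(right[root])});"


def phylo_from_arrays(left, right, root: int, labels) -> PhyloTree:
    return PhyloTree.from_newick(arrays_to_newick(left, right, root, labels))


def arrays_from_phylo(tree: PhyloTree, taxa) -> tuple:
    """Convert a binary PhyloTree to rooted arrays (leaf ids = taxa order)."""
    if set(tree.leaf_labels) != set(taxa):
        raise ValidationError("tree leaves must match the taxon list")
    if not tree.is_binary():
        raise ValidationError("array representation requires a binary tree")
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    rooted = tree.reroot_at(taxa[0])
    par, left, right = blank_arrays(n)
    root = 2 * n - 2
    next_internal = [n]

    def build(nd):
        if nd.is_leaf():
            return index[nd.taxon.label]
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise ValidationError("unexpected polytomy after rerooting")
        v = next_internal[0]
        next_internal[0] += 1
        a = build(kids[0])
        b = build(kids[1])
        left[v] = a
        right[v] = b
        par[a] = v
        par[b] = v
        return v

    seed = rooted.dendropy_tree.seed_node
    kids = seed.child_nodes()
    if len(kids) == 3:
        # degree-3 seed: split off the root leaf
        leaf_kid = next(
            k for k in kids if k.is_leaf() and k.taxon.label == taxa[0]
        )
        rest = [k for k in kids if k is not leaf_kid]
        v = next_internal[0]
        next_internal[0] += 1
        a = build(rest[0])
        b = build(rest[1])
        left[v] = a
        right[v] = b
        par[a] = v
        par[b] = v
        la, lb = index[taxa[0]], v
    elif len(kids) == 2:
        la = build(kids[0])
        lb = build(kids[1])
        if la != index[taxa[0]]:
            la, lb = (lb, la) if lb == index[taxa[0]] else (la, lb)
    else:
        raise ValidationError("unsupported root degree")
    left[root] = la
    right[root] = lb
    par[la] = root
    par[lb] = root
    return par, left, right, root


def enumerate_arrays(n: int):
    """Yield (par, left, right, root) for every unrooted binary topology.

    Leaves are ``0..n-1``; each topology is produced exactly once (the
    insertion-order construction is a bijection onto topologies).
    Arrays are reused between yields — copy if you keep them.
    """
    par, left, right = blank_arrays(n)
    root, w0 = init_triplet(par, left, right, 0, 1, 2, n)
    used = [1, 2, w0]  # candidate attachment edges; leaf 0 excluded

    def rec(z, next_internal):
        if z == n:
            yield par, left, right, root
            return
        for x in list(used):
            insert_leaf(par, left, right, x, z, next_internal)
            used.append(z)
            used.append(next_internal)
            yield from rec(z + 1, next_internal + 1)
            used.pop()
            used.pop()
            uninsert_leaf(par, left, right, x, next_internal)

    yield from rec(3, n + 1)


# ---------------------------------------------------------------------------
# adjacency form (slow generic path, used for TBR rearrangements)
# ---------------------------------------------------------------------------

def arrays_to_adjacency(par, left, right, root: int):
    """Unrooted adjacency map node -> set(neighbours), virtual root removed."""
    adj: dict = {}

    def link(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    M = left.shape[0]
    for v in range(M):
        if v == root or par[v] < 0:
            continue
        p = par[v]
        if p == root:
            continue
        link(v, p)
    link(int(left[root]), int(right[root]))
    return adj


def adjacency_to_arrays(adj, n: int):
    """Re-root an unrooted adjacency (binary) on leaf 0's pendant edge."""
    par, left, right = blank_arrays(n)
    root = 2 * n - 2
    nbr0 = next(iter(adj[0]))
    next_internal = [n]

    def build(v, parent):
        kids = [u for u in adj[v] if u != parent]
        if not kids:
            return v
        if len(kids) != 2:
            raise ValidationError("adjacency is not an unrooted binary tree")
        w = next_internal[0]
        next_internal[0] += 1
        a = build(kids[0], v)
        b = build(kids[1], v)
        left[w] = a
        right[w] = b
        par[a] = w
        par[b] = w
        return w

    b = build(nbr0, 0)
    left[root] = 0
    right[root] = b
    par[0] = root
    par[b] = root
    return par, left, right, root
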