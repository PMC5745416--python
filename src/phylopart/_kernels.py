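"""Numba-compiled parsimony scoring kernels.

Trees are passed as rooted binary array triples (par, left, right) over
``M = 2n - 1`` nodes: leaves are nodes ``0..n-1`` (node id == taxon row
in the matrix), internal nodes follow, and the (virtual) root is a fixed
node whose two children split the unrooted tree at one pendant edge.
Leaves have ``left == right == -1``.

The kernels rescore a whole tree for all characters in one call; the
heuristic search calls them once per candidate rearrangement, so they
are the innermost hot path of the permutation tests.
"""

import numpy as np
from numba import njit

BIG = np.int64(1) << 40


@njit(cache=False)
def fitch_score(root, left, right, masks, order, stack):
    """Total unordered parsimony steps over all characters.

    ``masks``: (M, C) int64 bitmask state sets; leaf rows prefilled by
    the caller (missing cells = union of the column's observed states),
    internal rows used as scratch.  ``order`` and ``stack`` are int64
    scratch arrays of length >= M.
    """
    # collect internal nodes in preorder; iterating it backwards visits
    # children before parents
    top = 0
    stack[top] = root
    top += 1
    cnt = 0
    while top > 0:
        top -= 1
        v = stack[top]
        if left[v] >= 0:
            order[cnt] = v
            cnt += 1
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1
    total = np.int64(0)
    C = masks.shape[1]
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        l = left[v]
        r = right[v]
        for c in range(C):
            inter = masks[l, c] & masks[r, c]
            if inter != 0:
                masks[v, c] = inter
            else:
                masks[v, c] = masks[l, c] | masks[r, c]
                total += 1
    return total


@njit(cache=False)
def fitch_steps(root, left, right, masks, order, stack, out):
    """Per-character unordered steps (same contract as fitch_score)."""
    top = 0
    stack[top] = root
    top += 1
    cnt = 0
    while top > 0:
        top -= 1
        v = stack[top]
        if left[v] >= 0:
            order[cnt] = v
            cnt += 1
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1
    C = masks.shape[1]
    for c in range(C):
        out[c] = 0
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        l = left[v]
        r = right[v]
        for c in range(C):
            inter = masks[l, c] & masks[r, c]
            if inter != 0:
                masks[v, c] = inter
            else:
                masks[v, c] = masks[l, c] | masks[r, c]
                out[c] += 1


@njit(cache=False)
def sankoff_linear_score(root, left, right, costs, order, stack):
    """Total ordered (linear-cost) steps over all characters.

    ``costs``: (M, C, K) int64; leaf rows prefilled with 0 at allowed
    states and BIG elsewhere (all 0 for missing).  Internal rows are
    scratch.  Transition cost between states i, j is |i - j|.
    """
    top = 0
    stack[top] = root
    top += 1
    cnt = 0
    while top > 0:
        top -= 1
        v = stack[top]
        if left[v] >= 0:
            order[cnt] = v
            cnt += 1
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1
    C = costs.shape[1]
    K = costs.shape[2]
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        l = left[v]
        r = right[v]
        for c in range(C):
            for s in range(K):
                bl = BIG
                br = BIG
                for t in range(K):
                    d = s - t if s >= t else t - s
                    cl = costs[l, c, t] + d
                    if cl < bl:
                        bl = cl
                    cr = costs[r, c, t] + d
                    if cr < br:
                        br = cr
                costs[v, c, s] = bl + br
    total = np.int64(0)
    for c in range(C):
        best = BIG
        for s in range(K):
            if costs[root, c, s] < best:
                best = costs[root, c, s]
        total += best
    return total


@njit(cache=False)
def subtree_masks(root, left, right, order, stack, out):
    """Leaf-set bitmask below every node (for bipartition extraction)."""
    top = 0
    stack[top] = root
    top += 1
    cnt = 0
    while top > 0:
        top -= 1
        v = stack[top]
        if left[v] >= 0:
            order[cnt] = v
            cnt += 1
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1
        else:
            out[v] = np.int64(1) << v
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        out[v] = out[left[v]] | out[right[v]]
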