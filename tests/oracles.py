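"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own dynamic programming, split
hashing and statistics: parsimony lengths come from exhaustive
enumeration of internal state assignments, RF distances from explicitly
enumerated splits, the MWW p-value from enumeration of rank
assignments, and the ANOVAs from hand-coded sums of squares.
"""

import itertools
import math
from math import comb

from phylopart.characters import MISSING


def brute_force_length(tree, taxa, column, ordering="unordered"):
    """Minimum steps by enumerating all internal-node state assignments."""
    dt = tree.dendropy_tree
    nodes = list(dt.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    observed = [c for c in column.cells if c is not MISSING]
    K = max(max(c) for c in observed) + 1 if observed else 1
    index = {t: i for i, t in enumerate(taxa)}

    def cost(i, j):
        if ordering == "ordered":
            return abs(i - j)
        return 0 if i == j else 1

    best = None
    for assign in itertools.product(range(K), repeat=len(internal)):
        amap = {id(nd): s for nd, s in zip(internal, assign)}
        total = 0
        for nd in nodes:
            if nd.parent_node is None:
                continue
            ps = amap[id(nd.parent_node)]
            if nd.is_leaf():
                cell = column.cells[index[nd.taxon.label]]
                if cell is MISSING:
                    continue
                total += min(cost(s, ps) for s in cell)
            else:
                total += cost(amap[id(nd)], ps)
        if best is None or total < best:
            best = total
    return best


def splits_of_tree(tree, order):
    """Nontrivial splits as frozensets of labels (slow explicit walk)."""
    dt = tree.dendropy_tree
    n = len(order)
    out = set()
    for nd in dt.postorder_node_iter():
        if nd.parent_node is None:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in nd.leaf_iter()
        )
        side = leaves if order[0] not in leaves else frozenset(order) - leaves
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def brute_rf(tree1, tree2):
    order = sorted(tree1.leaf_labels)
    a = splits_of_tree(tree1, order)
    b = splits_of_tree(tree2, order)
    return len(a ^ b)


def brute_nn_mean(trees_a, trees_b):
    d = [[brute_rf(x, y) for y in trees_b] for x in trees_a]
    vals = [min(row) for row in d]
    vals += [min(d[i][j] for i in range(len(trees_a)))
             for j in range(len(trees_b))]
    return sum(vals) / len(vals)


def exact_mww_p(a, b):
    """Two-sided MWW p by enumeration of all rank assignments (no ties)."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n_a, n_b = len(a), len(b)
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    mean_u = n_a * n_b / 2
    dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    all_ranks = list(range(1, n_a + n_b + 1))
    for combo in itertools.combinations(all_ranks, n_a):
        u = sum(combo) - n_a * (n_a + 1) / 2
        if abs(u - mean_u) >= dev - 1e-12:
            count += 1
        total += 1
    assert total == comb(n_a + n_b, n_a)
    return count / total


def anova_oneway_ss(samples):
    """(F, df_between, df_within) from hand-coded sums of squares."""
    allv = [v for s in samples for v in s]
    n = len(allv)
    grand = sum(allv) / n
    ss_between = sum(
        len(s) * (sum(s) / len(s) - grand) ** 2 for s in samples
    )
    ss_within = sum(
        (v - sum(s) / len(s)) ** 2 for s in samples for v in s
    )
    df_b = len(samples) - 1
    df_w = n - len(samples)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


def f_sf(f, df1, df2):
    """Upper tail of the F distribution via the regularized beta function."""
    x = df2 / (df2 + df1 * f)
    return _betainc_reg(df2 / 2.0, df1 / 2.0, x)


def _betainc_reg(a, b, x, steps=20000):
    # plain numerical integration; accurate enough for test tolerances
    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    total = 0.0
    for i in range(steps):
        t = x * (i + 0.5) / steps
        total += t ** (a - 1) * (1 - t) ** (b - 1)
    total *= x / steps
    lbeta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    return total / math.exp(lbeta)
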