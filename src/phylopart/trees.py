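"""Leaf-labelled phylogenetic topologies.

:class:`PhyloTree` is a thin immutable-by-convention wrapper over a
dendropy tree.  Trees are stored rooted (as parsed) but all comparisons
are unrooted: identity and distances are defined on the set of
nontrivial bipartitions of the leaf set.  Polytomies are preserved.
Branch lengths, when present in the source Newick, are retained for
simulation but ignored by parsimony scoring.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

from .errors import ParseError, ValidationError


class PhyloTree:
    """An unrooted-semantics phylogenetic tree with unique leaf labels."""

    __slots__ = ("_tree", "_leaves")

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValidationError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels: {dup}")
        if len(labels) < 2:
            raise ValidationError("a tree needs at least 2 leaves")
        self._leaves = tuple(labels)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser types
            msg = str(exc)
            if "Duplicate taxon labels" in msg or "Multiple occurrences" in msg:
                raise ValidationError(f"duplicate leaf labels: {msg}") from None
            raise ParseError(f"invalid Newick: {msg}") from None
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            text = fh.read().strip()
        if not text:
            raise ParseError("empty tree file", line=1)
        return cls.from_newick(text)

    @classmethod
    def star(cls, labels: Sequence[str]) -> "PhyloTree":
        """Star tree: one internal node joined to every leaf."""
        return cls.from_newick("(" + ",".join(labels) + ");")

    # -- basic accessors ------------------------------------------------

    @property
    def leaf_labels(self) -> tuple:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        """Underlying dendropy tree (treat as read-only)."""
        return self._tree

    def to_newick(self, lengths: bool = False) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=not lengths,
            unquoted_underscores=True,
        )
        return s.strip()

    def __repr__(self):
        return f"PhyloTree({self.to_newick()!r})"

    # -- topology -------------------------------------------------------

    def bipartition_masks(self, order: Sequence[str] | None = None) -> frozenset:
        """Nontrivial bipartitions as canonical leaf-index bitmasks.

        Each split is the bitmask of leaf indices (into ``order``, default
        the sorted leaf labels) on the side *not* containing ``order[0]``.
        Trivial splits (single leaf or its complement) are excluded.
        """
        if order is None:
            order = sorted(self._leaves)
        index = {lab: i for i, lab in enumerate(order)}
        if len(index) != len(order):
            raise ValidationError("order contains duplicates")
        for lab in self._leaves:
            if lab not in index:
                raise ValidationError(f"leaf {lab!r} missing from order")
        n = len(order)
        full = (1 << n) - 1
        splits = set()
        mask_of = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                m = 1 << index[nd.taxon.label]
            else:
                m = 0
                for ch in nd.child_nodes():
                    m |= mask_of[id(ch)]
            mask_of[id(nd)] = m
            if nd.parent_node is not None:
                c = m
                if c & 1:
                    c ^= full
                k = c.bit_count()
                if 2 <= k <= n - 2:
                    splits.add(c)
        return frozenset(splits)

    def topology_key(self):
        """Hashable unrooted-topology identity (leafset + splits)."""
        return (frozenset(self._leaves), self.bipartition_masks())

    def is_binary(self) -> bool:
        """True if fully resolved when regarded as unrooted."""
        root = self._tree.seed_node
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            k = len(nd.child_nodes())
            if nd is root:
                if k not in (2, 3):
                    return False
                # a rooted root with 2 children is an unrooted degree-3 node
            elif k != 2:
                return False
        return True

    def same_topology(self, other: "PhyloTree") -> bool:
        return self.topology_key() == other.topology_key()

    # -- manipulation (returns new trees) -------------------------------

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Restrict to the given leaves, suppressing degree-2 nodes."""
        keep = set(labels)
        absent = keep - set(self._leaves)
        if absent:
            raise ValidationError(f"leaves not in tree: {sorted(absent)}")
        if len(keep) < 2:
            raise ValidationError("cannot prune below 2 leaves")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        clone.suppress_unifurcations()
        # a leftover degree-1 seed node confuses downstream traversals
        while (
            not clone.seed_node.is_leaf()
            and len(clone.seed_node.child_nodes()) == 1
        ):
            clone.seed_node = clone.seed_node.child_nodes()[0]
            clone.seed_node.parent_node = None
        return PhyloTree(clone)

    def reroot_at(self, leaf_label: str) -> "PhyloTree":
        """Reroot on the pendant edge of the given leaf (topology unchanged)."""
        clone = self._tree.clone(depth=1)
        node = None
        for lf in clone.leaf_node_iter():
            if lf.taxon.label == leaf_label:
                node = lf
                break
        if node is None:
            raise ValidationError(f"no leaf {leaf_label!r}")
        clone.reroot_at_edge(node.edge, update_bipartitions=False)
        clone.suppress_unifurcations()
        return PhyloTree(clone)

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        )
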