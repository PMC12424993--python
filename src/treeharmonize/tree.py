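"""Rooted leaf-labelled phylogenies of clonal sublines.

The tree is the backbone of every placement and timing analysis: leaves are
single-cell-derived sublines, internal nodes are ancestral clones, and the
root's (conceptual) incoming branch is the trunk shared by all sublines.
Trees may be multifurcating; nothing here assumes a binary topology.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Sequence, Set

import dendropy


class TreeError(ValueError):
    """Malformed tree input or an unknown leaf label."""


class BranchClass(str, enum.Enum):
    """Evolutionary timing class of a node's incoming branch.

    ``truncal``: the trunk above the root (shared by every subline);
    ``terminal``: the branch leading to a leaf (private to one subline);
    ``internal``: everything else (subclonal).
    """

    TRUNCAL = "truncal"
    INTERNAL = "internal"
    TERMINAL = "terminal"


@dataclass
class Phylogeny:
    """Rooted tree with unique, non-empty leaf labels.

    Node identifiers are strings: a leaf's identifier is its subline label;
    internal nodes get deterministic preorder identifiers ``n0, n1, ...``
    (``n0`` is the root) unless the input names them.
    """

    root: str
    children: Dict[str, List[str]]
    parent: Dict[str, str]
    leaf_labels: List[str]

    _leaves_below: Dict[str, FrozenSet[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"newick parse failure: {exc}") from exc
        return cls._from_dendropy(dtree)

    @classmethod
    def read_newick(cls, path: str) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        children: Dict[str, List[str]] = {}
        parent: Dict[str, str] = {}
        leaf_labels: List[str] = []
        counter = 0
        ids: Dict[int, str] = {}

        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else node.label
                if not label:
                    raise TreeError("unlabeled leaf in newick input")
                ident = str(label)
                leaf_labels.append(ident)
            else:
                ident = f"n{counter}"
                counter += 1
            ids[id(node)] = ident
            children.setdefault(ident, [])
            if node.parent_node is not None:
                pid = ids[id(node.parent_node)]
                children[pid].append(ident)
                parent[ident] = pid

        if len(set(leaf_labels)) != len(leaf_labels):
            raise TreeError("duplicate leaf labels")
        root = ids[id(dtree.seed_node)]
        return cls(root=root, children=children, parent=parent, leaf_labels=leaf_labels)

    # -- traversal ---------------------------------------------------------

    def nodes(self) -> List[str]:
        """All node identifiers in preorder."""
        out: List[str] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children[n]))
        return out

    def is_leaf(self, node: str) -> bool:
        return not self.children[node]

    def level_order(self) -> List[str]:
        """Root-to-leaves breadth-first order."""
        out = [self.root]
        i = 0
        while i < len(out):
            out.extend(self.children[out[i]])
            i += 1
        return out

    def reverse_level_order(self) -> List[str]:
        """Leaves-to-root breadth-first order (deepest level first)."""
        return list(reversed(self.level_order()))

    def depth(self, node: str) -> int:
        d = 0
        while node != self.root:
            node = self.parent[node]
            d += 1
        return d

    # -- leaf sets and MRCA ------------------------------------------------

    def leaves_below(self, node: str) -> FrozenSet[str]:
        """Leaf labels in the subtree rooted at ``node`` (cached)."""
        cached = self._leaves_below.get(node)
        if cached is not None:
            return cached
        if self.is_leaf(node):
            result: FrozenSet[str] = frozenset([node])
        else:
            acc: Set[str] = set()
            for c in self.children[node]:
                acc |= self.leaves_below(c)
            result = frozenset(acc)
        self._leaves_below[node] = result
        return result

    def clade_size(self, node: str) -> int:
        return len(self.leaves_below(node))

    def mrca(self, leaves: Iterable[str]) -> str:
        """Deepest node whose subtree leaf set contains every given label."""
        labels = set(leaves)
        if not labels:
            raise TreeError("mrca of an empty leaf set")
        unknown = labels - set(self.leaf_labels)
        if unknown:
            raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
        if len(labels) == 1:
            return next(iter(labels))
        # Walk up from an arbitrary member until the subtree covers all labels.
        node = next(iter(labels))
        while not labels <= self.leaves_below(node):
            node = self.parent[node]
        return node

    def classify_branch(self, node: str) -> BranchClass:
        """Timing class of the branch above ``node``.

        The trunk is not an explicit edge; placement "at the trunk" is
        placement at the root node itself.
        """
        if node == self.root:
            return BranchClass.TRUNCAL
        if self.is_leaf(node):
            return BranchClass.TERMINAL
        return BranchClass.INTERNAL

    def ancestors(self, node: str) -> List[str]:
        """Strict ancestors of ``node``, nearest first."""
        out = []
        while node != self.root:
            node = self.parent[node]
            out.append(node)
        return out

    def path_from_root(self, node: str) -> List[str]:
        """Nodes on the root→node path, root first, ``node`` last."""
        return list(reversed(self.ancestors(node))) + [node]

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: str) -> str:
            if self.is_leaf(node):
                return node
            inner = ",".join(render(c) for c in self.children[node])
            return f"({inner})"

        return render(self.root) + ";"

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")
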