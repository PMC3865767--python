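"""Phylogenetic tree structure shared by the simulator, BIONJ and SLAC stages.

The internal representation is a plain parent/child node graph with branch
lengths in substitutions per site and optional bootstrap supports (0-100) on
internal edges. Newick syntax is parsed and serialised through dendropy so
the package never hand-rolls the grammar; supports travel as internal-node
labels, the convention the rest of the field uses.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None):
        if length < 0:
            raise TreeError(f"negative branch length {length} on node {name!r}")
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, len={self.length:g}, kids={len(self.children)})"


class PhyloTree:
    """Rooted view of a phylogeny; a trifurcating root encodes the unrooted case."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise TreeError("duplicate leaf labels")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self, scale: Callable[[float], float] | None = None) -> "PhyloTree":
        def dup(node: TreeNode) -> TreeNode:
            length = node.length if scale is None else scale(node.length)
            new = TreeNode(node.name, length, node.support)
            for child in node.children:
                new.add_child(dup(child))
            return new

        return PhyloTree(dup(self.root))

    def relabel_leaves(self, fn: Callable[[str], str]) -> None:
        for leaf in self.leaves():
            leaf.name = fn(leaf.name)

    # -- metrics -----------------------------------------------------------
    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def root_to_tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                depths[node.name] = acc
            for child in node.children:
                walk(child, acc)

        walk(self.root, -self.root.length)
        return depths

    def path_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (labels in leaf order)."""
        leaves = self.leaves()
        labels = [n.name for n in leaves]
        index = {id(n): i for i, n in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[id(node)]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for child in node.children:
                cm = {k: v + child.length for k, v in walk(child).items()}
                child_maps.append(cm)
            for m1, m2 in itertools.combinations(child_maps, 2):
                for i, di in m1.items():
                    for j, dj in m2.items():
                        d[i, j] = d[j, i] = di + dj
            for cm in child_maps:
                below.update(cm)
            return below

        walk(self.root)
        return labels, d

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial leaf bipartitions, each as the canonical smaller/sorted side."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return splits

    # -- newick ------------------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    sup = node.support
                    label += f"{sup:g}" if sup != int(sup) else f"{int(sup)}"
            if node is self.root:
                return label
            return f"{label}:{node.length:.{precision}g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise TreeError(f"duplicate leaf labels: {exc}") from exc
        except Exception as exc:  # malformed newick (unbalanced parens, ...)
            raise TreeError(f"malformed newick: {exc}") from exc

        def convert(dnode) -> TreeNode:
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
                return TreeNode(name, length)
            support = None
            if dnode.label not in (None, ""):
                try:
                    support = float(dnode.label)
                except ValueError:
                    support = None
            node = TreeNode(None, length, support)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
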