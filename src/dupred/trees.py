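"""Rooted phylogenetic trees with branch lengths.

A single light-weight tree container serves both gene trees and the species
tree.  Newick grammar handling is delegated to dendropy; this module adds the
validation the analysis relies on (unique leaf names, non-negative branch
lengths) and the LCA / root-to-leaf path arithmetic used to date duplication
events.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

from .errors import NewickError

__all__ = ["TreeNode", "PhyloTree", "parse_newick"]


class TreeNode:
    """One node of a rooted tree.

    ``length`` is the branch length to the parent (``None`` on the root or
    when the input carried no length).
    """

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator["TreeNode"]:
        for node in self.preorder():
            if node.is_leaf:
                yield node

    def ancestors(self, include_self: bool = False) -> Iterator["TreeNode"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r})"


class PhyloTree:
    """A rooted tree with named leaves and branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._leaf_map: Optional[dict[str, TreeNode]] = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        parts: list[str] = []

        def write(node: TreeNode) -> None:
            if node.children:
                parts.append("(")
                for i, child in enumerate(node.children):
                    if i:
                        parts.append(",")
                    write(child)
                parts.append(")")
            if node.name:
                parts.append(node.name)
            if node.length is not None:
                parts.append(f":{node.length:.12g}")

        write(self.root)
        parts.append(";")
        return "".join(parts)

    # -- queries ----------------------------------------------------------

    @property
    def leaf_map(self) -> dict[str, TreeNode]:
        if self._leaf_map is None:
            self._leaf_map = {leaf.name: leaf for leaf in self.root.leaves()}
        return self._leaf_map

    def leaves(self) -> list[TreeNode]:
        return list(self.root.leaves())

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def leaf(self, name: str) -> TreeNode:
        try:
            return self.leaf_map[name]
        except KeyError:
            raise KeyError(f"leaf {name!r} not found in tree") from None

    def node(self, name: str) -> TreeNode:
        """Return the (first, preorder) node with this label, leaf or internal."""
        for n in self.root.preorder():
            if n.name == name:
                return n
        raise KeyError(f"node {name!r} not found in tree")

    def lca(self, nodes: Iterable[TreeNode | str]) -> TreeNode:
        """Last common ancestor of a set of nodes (multifurcations allowed)."""
        resolved = [self.leaf(n) if isinstance(n, str) else n for n in nodes]
        if not resolved:
            raise ValueError("lca() requires at least one node")
        it = iter(resolved)
        anc = next(it)
        anc_set = {id(a) for a in anc.ancestors(include_self=True)}
        current = anc
        for node in it:
            walker: Optional[TreeNode] = node
            while walker is not None and id(walker) not in anc_set:
                walker = walker.parent
            if walker is None:
                raise ValueError("nodes do not share a common ancestor")
            current = walker
            anc_set = {id(a) for a in current.ancestors(include_self=True)}
        return current

    def path_length(self, ancestor: TreeNode, descendant: TreeNode) -> float:
        """Sum of branch lengths on the path from ``ancestor`` down to ``descendant``."""
        total = 0.0
        node = descendant
        while node is not ancestor:
            if node.parent is None:
                raise ValueError(
                    f"{ancestor.name!r} is not an ancestor of {descendant.name!r}"
                )
            total += node.length or 0.0
            node = node.parent
        return total

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        names = self.leaf_names()
        shown = ",".join(names[:4]) + ("..." if len(names) > 4 else "")
        return f"PhyloTree({len(names)} leaves: {shown})"


def _convert(dnode: dendropy.Node) -> TreeNode:
    if dnode.taxon is not None:
        name = dnode.taxon.label
    else:
        name = dnode.label
    node = TreeNode(name=name, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_convert(child))
    return node


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Raises :class:`NewickError` (with the parser's position information when
    available) on malformed input, duplicate leaf names, or negative branch
    lengths.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc

    root = _convert(dtree.seed_node)
    # Root branch length is ignored by every downstream computation but kept
    # for round-tripping.
    tree = PhyloTree(root)

    names = [leaf.name for leaf in root.leaves()]
    if any(n is None for n in names):
        raise NewickError("tree contains an unnamed leaf")
    seen: set[str] = set()
    dups: set[str] = set()
    for n in names:
        if n in seen:
            dups.add(n)
        seen.add(n)
    if dups:
        raise NewickError(f"duplicate leaf names: {sorted(dups)}")
    for node in root.preorder():
        if node.length is not None and node.length < 0:
            raise NewickError(
                f"negative branch length {node.length} at node {node.name!r}"
            )
    return tree
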