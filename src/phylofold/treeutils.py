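"""A small rooted/unrooted phylogenetic tree container.

Nodes carry a label, a branch length (to the parent), and an optional
bootstrap support in [0, 100] for internal nodes.  Unrooted trees are stored
with a degree-3 (or higher) pseudo-root.  Newick text is parsed with
dendropy; writing is a plain recursive serialization with quoting where the
label demands it.

Supports are a property of bipartitions, not of node identities: rerooting
reassigns them from the tree's bipartition -> support map so they survive any
change of root.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import dendropy

__all__ = ["Node", "PhyloTree"]


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`+<>]")


def _fmt_label(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class PhyloTree:
    """Tree with tip labels, branch lengths and optional internal supports."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dn) -> Node:
            if dn.taxon is not None:
                label = dn.taxon.label
            else:
                label = dn.label
            n = Node(label=label, length=dn.edge.length)
            # an internal label that parses as a number is a support value
            if dn.child_nodes() and label is not None:
                try:
                    n.support = float(label)
                    n.label = None
                except ValueError:
                    pass
            for dc in dn.child_nodes():
                n.add(convert(dc))
            return n

        root = convert(dt.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    @classmethod
    def read(cls, path: str | Path, rooted: bool | None = None) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text(), rooted=rooted)

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(label=n.label, length=n.length, support=n.support)
            for c in n.children:
                m.add(dup(c))
            return m

        return PhyloTree(dup(self.root), rooted=self.rooted)

    # -- queries -----------------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def find_leaf(self, label: str) -> Node:
        for n in self.root.leaves():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not in tree")

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def is_binary(self) -> bool:
        return all(
            len(n.children) in (0, 2)
            for n in self.postorder()
            if n is not self.root
        ) and len(self.root.children) == (2 if self.rooted else 3)

    # -- serialization -----------------------------------------------------

    def to_newick(
        self,
        lengths: bool = True,
        supports: bool = True,
        length_format: str = "%.10g",
    ) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = _fmt_label(n.label or "")
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if supports and n.support is not None:
                    s += (length_format % n.support)
                elif n.label:
                    s += _fmt_label(n.label)
            if lengths and n.length is not None and n.parent_exists:
                s += ":" + (length_format % n.length)
            return s

        # mark which nodes have a parent edge worth printing
        for n in self.postorder():
            n.parent_exists = n.parent is not None
        return fmt(self.root) + ";"

    def write(self, path: str | Path, **kw) -> None:
        Path(path).write_text(self.to_newick(**kw) + "\n")

    # -- relabeling --------------------------------------------------------

    def relabel_tips(self, fn: Callable[[str], str]) -> "PhyloTree":
        t = self.copy()
        for leaf in t.root.leaves():
            leaf.label = fn(leaf.label)
        return t
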