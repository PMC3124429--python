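"""Topological tree comparison via the Robinson-Foulds metric.

Each internal edge of the unrooted tree induces a bipartition of the leaf
set; the (unweighted) Robinson-Foulds distance between two trees on the same
leaves is the size of the symmetric difference of their bipartition sets.
Splits are stored canonically as the side *not* containing a fixed reference
leaf (the lexicographically smallest label), which makes the representation
independent of rooting and rotation.  Trivial splits (a single leaf against
the rest) are excluded.

Gene trees usually carry several tips per species; :func:`prune_to_unique`
reduces them to one tip per species before comparison with a species tree.
"""

from __future__ import annotations

from typing import Mapping

from .treeutils import Node, PhyloTree

__all__ = [
    "bipartitions",
    "robinson_foulds",
    "rf_detail",
    "prune_to_unique",
]


def _canonical(side: frozenset, universe: frozenset) -> frozenset:
    """Store the side of the split not containing the reference leaf."""
    ref = min(universe)
    return universe - side if ref in side else side


def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial splits of the unrooted version of the tree.

    One split per internal edge; the root (rooted trees have a degree-2 root
    whose two edges induce the same split) contributes no duplicate.
    """
    universe = frozenset(tree.leaf_labels())
    out: set[frozenset] = set()
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        below = frozenset(l.label for l in node.leaves())
        if 1 < len(below) < len(universe) - 1:
            out.add(_canonical(below, universe))
    return out


def robinson_foulds(
    t1: PhyloTree,
    t2: PhyloTree,
    mapping: Mapping[str, str] | None = None,
) -> int:
    """Unweighted Robinson-Foulds distance.

    ``mapping`` relabels the tips of ``t1`` (typically gene tip -> species)
    before comparison; after relabeling both trees must have identical leaf
    sets.
    """
    if mapping is not None:
        t1 = t1.relabel_tips(lambda l: mapping.get(l, l))
    u1 = frozenset(t1.leaf_labels())
    u2 = frozenset(t2.leaf_labels())
    if u1 != u2:
        raise ValueError(
            "leaf sets differ: only in first "
            f"{sorted(u1 - u2)}, only in second {sorted(u2 - u1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def rf_detail(
    t1: PhyloTree,
    t2: PhyloTree,
    mapping: Mapping[str, str] | None = None,
) -> dict:
    """RF distance with shared/unique split counts (JSON-friendly)."""
    if mapping is not None:
        t1 = t1.relabel_tips(lambda l: mapping.get(l, l))
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return {
        "rf": len(b1 ^ b2),
        "n_splits_tree1": len(b1),
        "n_splits_tree2": len(b2),
        "shared": len(b1 & b2),
        "unique_to_tree1": len(b1 - b2),
        "unique_to_tree2": len(b2 - b1),
        "max_rf": len(b1) + len(b2),
    }


def prune_to_unique(
    tree: PhyloTree,
    mapping: Mapping[str, str],
    keep: Mapping[str, str] | None = None,
) -> PhyloTree:
    """Prune a gene tree to one tip per species.

    ``mapping`` sends gene tips to species; ``keep`` names, for each species
    with several tips, the gene tip to retain.  Species with multiple tips
    and no ``keep`` entry raise an error.
    """
    keep = keep or {}
    by_species: dict[str, list[str]] = {}
    for label in tree.leaf_labels():
        by_species.setdefault(mapping.get(label, label), []).append(label)
    retain: set[str] = set()
    for sp, tips in by_species.items():
        if len(tips) == 1:
            retain.add(tips[0])
        elif sp in keep:
            if keep[sp] not in tips:
                raise ValueError(f"keep[{sp!r}]={keep[sp]!r} is not a tip of that species")
            retain.add(keep[sp])
        else:
            raise ValueError(
                f"species {sp!r} has multiple tips {sorted(tips)}; "
                "specify which to keep"
            )
    t = tree.copy()
    # iteratively remove unwanted leaves, suppressing unifurcations
    changed = True
    while changed:
        changed = False
        for node in list(t.postorder()):
            if node.is_leaf and node.label not in retain and node is not t.root:
                node.parent.children.remove(node)
                changed = True
        # suppress internal nodes with a single child
        for node in list(t.postorder()):
            if node.is_leaf or node is t.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                par = node.parent
                par.children[par.children.index(node)] = child
                child.parent = par
                changed = True
        if len(t.root.children) == 1:
            only = t.root.children[0]
            if not only.is_leaf:
                only.parent = None
                only.length = None
                t.root = only
                changed = True
    return PhyloTree(t.root, rooted=t.rooted)
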