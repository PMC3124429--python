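"""Distance-based protein tree building.

Pairwise distances are maximum-likelihood branch lengths under a reversible
empirical model (JTT by default): for two aligned rows the distance is the
t >= 0 maximizing sum over shared non-gap sites of log[pi_a * P(t)_{ab}],
with P(t) from the model's spectral decomposition.  Trees are built by
Saitou-Nei neighbor joining; node reliability comes from column-resampling
bootstrap, and rooting is by a user-chosen outgroup (the most basal species'
protein), with the root placed at the midpoint of the outgroup's pendant
edge.

Tip labels can be decorated with the residues observed at "tracked"
alignment columns (e.g. ``WL_B2MG_RAJEG``), giving a close-up of the
evolution of individual sites on the tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .family_io import Alignment, GAP, extract_column_states
from .substmodel import SubstitutionModel, jtt_model
from .tree_compare import bipartitions, _canonical
from .treeutils import Node, PhyloTree

__all__ = [
    "SaturationWarning",
    "DistanceMatrix",
    "jtt_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "reroot",
    "annotate_tips_with_site_states",
]

logger = logging.getLogger(__name__)

MAX_DISTANCE = 10.0  # substitutions/site; beyond this the signal is saturated


class SaturationWarning(UserWarning):
    """Estimated distance hit the search bound: sequences are saturated."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.8g"
        )


def _pair_counts(a: str, b: str, model: SubstitutionModel) -> np.ndarray:
    """20x20 matrix of site counts over shared non-gap, known-residue columns."""
    C = np.zeros((20, 20))
    for x, y in zip(a, b):
        if x in (GAP, "X") or y in (GAP, "X"):
            continue
        C[model.state_index(x), model.state_index(y)] += 1
    return C


def jtt_distance(
    a: str, b: str, model: SubstitutionModel | None = None
) -> float:
    """ML distance (substitutions/site) between two gapped rows.

    The likelihood is optimized over t in [0, MAX_DISTANCE]; a distance at
    the upper bound raises :class:`SaturationWarning`.  Identical overlapping
    sites give exactly 0.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal (aligned) length")
    model = model or jtt_model()
    C = _pair_counts(a, b, model)
    n_sites = C.sum()
    if n_sites == 0:
        raise ValueError("no overlap: sequences share no non-gap columns")
    if np.trace(C) == n_sites:
        return 0.0
    # detailed balance makes the likelihood invariant under transposing the
    # pair counts; symmetrizing makes that exact in floating point too
    C = (C + C.T) / 2
    log_pi = np.log(model.pi)

    def nll(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = C * (log_pi[:, None] + np.log(P))
        return -np.sum(ll[C > 0])

    res = minimize_scalar(
        nll, bounds=(0.0, MAX_DISTANCE), method="bounded",
        options={"xatol": 1e-10},
    )
    t = float(res.x)
    if t > MAX_DISTANCE - 1e-4:
        warnings.warn(
            f"distance at saturation bound {MAX_DISTANCE}", SaturationWarning,
            stacklevel=2,
        )
        t = MAX_DISTANCE
    return t


def distance_matrix(
    aln: Alignment, model: SubstitutionModel | None = None
) -> DistanceMatrix:
    if len(aln) < 3:
        raise ValueError("need at least 3 sequences")
    model = model or jtt_model()
    ids = aln.ids
    n = len(ids)
    d = np.zeros((n, n))
    bad = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = jtt_distance(
                    aln.records[i].residues, aln.records[j].residues, model
                )
            except ValueError:
                bad.append((ids[i], ids[j]))
    if bad:
        raise ValueError(f"pairs with no shared non-gap columns: {bad}")
    return DistanceMatrix(labels=list(ids), d=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; returns an unrooted tree (degree-3 root).

    Ties in the Q criterion break on the smallest (row, column) index pair in
    the current label order; negative branch-length estimates are clamped to
    zero with the deficit logged.
    """
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[Node] = [Node(label=l) for l in dm.labels]
    d = dm.d.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("clamped negative NJ branch length %.6g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q, ties by smallest (row, col)
        best = np.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best - 1e-15:
                    best, bi, bj = q[i, j], i, j
        gi, gj = active[bi], active[bj]
        dij = sub[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        u = Node()
        ni, nj_ = nodes[gi], nodes[gj]
        ni.length = clamp(li)
        nj_.length = clamp(lj)
        u.add(ni)
        u.add(nj_)
        # distances from u to every other active node
        new_row = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.vstack([d, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        d = np.hstack([d, new_col[:, None]])
        nodes.append(u)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # join final three analytically
    a, b, c = active
    root = Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for g, L in ((a, la), (b, lb), (c, lc)):
        nodes[g].length = clamp(L)
        root.add(nodes[g])
    return PhyloTree(root, rooted=False)


def bootstrap_support(
    aln: Alignment,
    model: SubstitutionModel | None = None,
    replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap supports (percent of replicates) on internal
    nodes.

    Columns are resampled with replacement per replicate; replicates whose
    resampled alignment leaves some pair without overlap are dropped and
    counted (warning if more than 5% are dropped).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    model = model or jtt_model()
    point = nj_tree(distance_matrix(aln, model))
    universe = frozenset(point.leaf_labels())
    target = {s: 0 for s in bipartitions(point)}

    rng = np.random.default_rng(seed)
    n_cols = aln.n_columns
    dropped = 0
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        from .family_io import Alignment as _Aln, SequenceRecord as _Rec

        boot = _Aln(
            [
                _Rec(
                    id=r.id,
                    residues="".join(r.residues[c] for c in cols),
                    species=r.species,
                    is_fragment=r.is_fragment,
                )
                for r in aln.records
            ]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SaturationWarning)
                t = nj_tree(distance_matrix(boot, model))
        except ValueError:
            dropped += 1
            continue
        done += 1
        for s in bipartitions(t):
            if s in target:
                target[s] += 1
    if dropped > 0.05 * replicates:
        warnings.warn(
            f"{dropped}/{replicates} bootstrap replicates dropped", stacklevel=2
        )
    if done == 0:
        raise ValueError("all bootstrap replicates failed")
    supported = point.copy()
    for node in supported.postorder():
        if node.is_leaf or node is supported.root:
            continue
        split = _canonical(
            frozenset(l.label for l in node.leaves()), universe
        )
        if split in target:
            node.support = 100.0 * target[split] / done
    return supported


def reroot(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root the tree on the outgroup's pendant edge (at its midpoint).

    Bootstrap supports are treated as properties of bipartitions and are
    reassigned to the corresponding edges of the rerooted tree.
    """
    universe = frozenset(tree.leaf_labels())
    # bipartition -> support, from the input tree
    sup_map: dict[frozenset, float] = {}
    for node in tree.postorder():
        if node.is_leaf or node is tree.root or node.support is None:
            continue
        sup_map[
            _canonical(frozenset(l.label for l in node.leaves()), universe)
        ] = node.support

    t = tree.copy()
    leaf = t.find_leaf(outgroup)
    u = leaf.parent
    if u is None:
        raise ValueError("cannot reroot a single-tip tree")
    L = leaf.length if leaf.length is not None else 0.0

    path = []
    node = u
    while node is not None:
        path.append(node)
        node = node.parent

    u.children.remove(leaf)
    leaf.parent = None
    new_root = Node()
    leaf.length = L / 2
    new_root.add(leaf)
    new_root.add(u)

    pending = L / 2
    for i, node in enumerate(path):
        orig = node.length
        node.length = pending
        pending = orig
        if i + 1 < len(path):
            par = path[i + 1]
            par.children.remove(node)
            node.add(par)

    old_root = path[-1]
    if len(old_root.children) == 1:
        par = old_root.parent
        child = old_root.children[0]
        child.length = (child.length or 0.0) + (old_root.length or 0.0)
        child.parent = None
        par.children.remove(old_root)
        par.add(child)

    out = PhyloTree(new_root, rooted=True)
    for node in out.postorder():
        if node.is_leaf or node is out.root:
            continue
        node.support = sup_map.get(
            _canonical(frozenset(l.label for l in node.leaves()), universe)
        )
    return out


def annotate_tips_with_site_states(
    tree: PhyloTree,
    aln: Alignment,
    columns: Sequence[int],
    separator: str = "_",
) -> PhyloTree:
    """Prefix each tip label with its one-letter states at the tracked
    columns (e.g. ``WL_B2MG_RAJEG``); gaps appear as '-'."""
    if not columns:
        return tree.copy()
    states = [extract_column_states(aln, c) for c in columns]
    ids = set(aln.ids)
    for label in tree.leaf_labels():
        if label not in ids:
            raise ValueError(f"tip {label!r} has no sequence in the alignment")
    return tree.relabel_tips(
        lambda l: "".join(s[l] for s in states) + separator + l
    )
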