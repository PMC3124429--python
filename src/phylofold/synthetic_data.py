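"""Ground-truth simulators for every stage of the pipeline.

Gene families are grown along a rooted species tree: each gene lineage
accumulates duplication and loss events as Poisson processes (rates per unit
of species-tree branch length); a duplication copies the subtending lineage,
a loss prunes it, and speciations follow the species tree.  Sequences then
evolve site-independently down the true gene tree under a reversible
substitution model (JTT by default) with optional gamma rate variation,
using exact transition probabilities per branch.  A designated "tracked"
column can be overwritten post hoc with clade-specific states (e.g. Leu in a
basal clade, Trp elsewhere), giving a deterministic target for the
annotation and ancestral-reconstruction stages.

Biophysics presets generate equilibrium denaturation curves and kinetic
traces whose true parameters are the experimentally characterized values for
wild-type and Trp95Leu beta-2-microglobulin: equilibrium midpoints 1.9 and
1.65 M GdnHCl (a 1.0 kcal/mol destabilization with a shared m-value of 4.0
kcal/mol/M), folding phases at 1.65 and 0.003 1/s, and unfolding at 0.22
(wild type) and 0.4 (variant) 1/s at 5.1 M GdnHCl.

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .family_io import Alignment, SequenceRecord
from .foldstab import DenaturationCurve, KineticTrace, santoro_bolen_signal
from .substmodel import SubstitutionModel, jtt_model
from .treeutils import Node, PhyloTree

__all__ = [
    "TrackedSite",
    "FamilySimSpec",
    "SimulatedFamily",
    "simulate_family",
    "simulate_sequences",
    "default_species_tree",
    "CurveSimSpec",
    "TraceSimSpec",
    "EQUILIBRIUM_PRESETS",
    "TRACE_PRESETS",
    "simulate_denaturation",
    "simulate_trace",
]


# --------------------------------------------------------------------------
# gene family simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackedSite:
    """A column whose tip states are pinned per species after simulation.

    ``states`` maps species label -> one-letter state; species absent from
    the map keep ``default_state``.  ``root_state`` records the intended
    ancestral state (written into the true root sequence).
    """

    column: int  # 1-based
    states: Mapping[str, str]
    default_state: str = "W"
    root_state: str | None = None


@dataclass
class FamilySimSpec:
    species_tree: PhyloTree
    seq_length: int = 200
    model: SubstitutionModel | None = None
    alpha: float | None = None  # gamma shape; None = uniform rates
    dup_rate: float = 0.0  # events per unit branch length
    loss_rate: float = 0.0
    tracked_site: TrackedSite | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.tracked_site and not (
            1 <= self.tracked_site.column <= self.seq_length
        ):
            raise ValueError("tracked column outside the sequence")


@dataclass
class SimulatedFamily:
    alignment: Alignment  # gap-free
    true_gene_tree: PhyloTree  # rooted
    events: list[tuple]  # (type, species branch label, time along branch)
    true_root_sequence: str
    tip_mapping: dict[str, str]  # gene tip -> species
    seed: int = 0

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e[0] == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e[0] == "loss")


def default_species_tree() -> PhyloTree:
    """An 8-species rooted tree with a basal outgroup (RAJEG), emulating the
    shape of a vertebrate family with cartilaginous fish at the base."""
    nwk = (
        "(RAJEG:0.5,((DANRE:0.25,ONCMY:0.25):0.15,((XENLA:0.3,"
        "(CHICK:0.15,ANAPL:0.15):0.15):0.05,(HUMAN:0.1,MOUSE:0.1):0.25)"
        ":0.05):0.15);"
    )
    return PhyloTree.from_newick(nwk, rooted=True)


def _species_label(node: Node) -> str:
    return node.label or "?"


def _grow(
    sp_node: Node,
    remaining: float,
    spec: FamilySimSpec,
    rng: np.random.Generator,
    events: list,
    branch_label: str,
    elapsed: float,
) -> Node | None:
    """One gene lineage travelling down a species branch; returns the gene
    subtree it founds (with .length measured from the entry point), or None
    if every descendant copy is lost."""
    total_rate = spec.dup_rate + spec.loss_rate
    t_event = (
        rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
    )
    if t_event < remaining:
        if rng.random() < spec.dup_rate / total_rate:
            events.append(("duplication", branch_label, elapsed + t_event))
            left = _grow(
                sp_node, remaining - t_event, spec, rng, events,
                branch_label, elapsed + t_event,
            )
            right = _grow(
                sp_node, remaining - t_event, spec, rng, events,
                branch_label, elapsed + t_event,
            )
            survivors = [c for c in (left, right) if c is not None]
            if not survivors:
                return None
            if len(survivors) == 1:
                only = survivors[0]
                only.length += t_event
                return only
            node = Node(length=t_event)
            for c in survivors:
                node.add(c)
            return node
        events.append(("loss", branch_label, elapsed + t_event))
        return None
    # reached the species node
    if sp_node.is_leaf:
        return Node(label=_species_label(sp_node), length=remaining)
    kids = []
    for child in sp_node.children:
        sub = _grow(
            child, child.length or 0.0, spec, rng, events,
            f"{_species_label(sp_node)}->{_species_label(child)}"
            if child.label
            else f"branch_above_{_species_label(child)}",
            0.0,
        )
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        kids[0].length += remaining
        return kids[0]
    node = Node(length=remaining)
    for c in kids:
        node.add(c)
    return node


def simulate_sequences(
    tree: PhyloTree,
    seq_length: int,
    model: SubstitutionModel,
    alpha: float | None,
    rng: np.random.Generator,
) -> tuple[dict[str, str], str]:
    """Evolve sequences down a rooted tree; returns (tip sequences by label,
    root sequence).  Per-site rates are continuous gamma(alpha, 1/alpha)
    draws when alpha is set, else 1."""
    n_states = len(model.pi)
    root_states = rng.choice(n_states, size=seq_length, p=model.pi)
    rates = (
        rng.gamma(alpha, 1.0 / alpha, size=seq_length)
        if alpha is not None
        else None
    )
    seqs: dict[int, np.ndarray] = {id(tree.root): root_states}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = seqs[id(node.parent)]
        t = node.length or 0.0
        child = np.empty(seq_length, dtype=np.int64)
        if rates is None:
            P = model.transition_matrix(t)
            cum = np.cumsum(P, axis=1)
            u = rng.random(seq_length)
            for s_idx in range(n_states):
                mask = parent_states == s_idx
                if mask.any():
                    child[mask] = np.searchsorted(cum[s_idx], u[mask])
        else:
            u = rng.random(seq_length)
            for i in range(seq_length):
                P = model.transition_matrix(t * rates[i])
                child[i] = np.searchsorted(
                    np.cumsum(P[parent_states[i]]), u[i]
                )
        np.clip(child, 0, n_states - 1, out=child)
        seqs[id(node)] = child

    def to_str(states: np.ndarray) -> str:
        return "".join(model.states[i] for i in states)

    tips = {n.label: to_str(seqs[id(n)]) for n in tree.root.leaves()}
    return tips, to_str(root_states)


def simulate_family(spec: FamilySimSpec) -> SimulatedFamily:
    """Grow a gene family along the species tree and evolve its sequences."""
    model = spec.model or jtt_model()
    rng = np.random.default_rng(spec.seed)
    events: list[tuple] = []
    sp_root = spec.species_tree.root
    kids = []
    for child in sp_root.children:
        sub = _grow(
            child, child.length or 0.0, spec, rng, events,
            f"root->{_species_label(child)}", 0.0,
        )
        if sub is not None:
            kids.append(sub)
    if not kids:
        raise ValueError("empty family, adjust rates/seed")
    if len(kids) == 1:
        gene_root = kids[0]
        gene_root.length = None
        gene_root.parent = None
    else:
        gene_root = Node()
        for c in kids:
            gene_root.add(c)

    # unique tip labels G<i>_<species>; record mapping
    counts: dict[str, int] = {}
    mapping: dict[str, str] = {}
    for leaf in gene_root.leaves():
        sp = leaf.label
        counts[sp] = counts.get(sp, 0) + 1
        leaf.label = f"G{counts[sp]}_{sp}"
        mapping[leaf.label] = sp
    gene_tree = PhyloTree(gene_root, rooted=True)

    tips, root_seq = simulate_sequences(
        gene_tree, spec.seq_length, model, spec.alpha, rng
    )

    if spec.tracked_site is not None:
        ts = spec.tracked_site
        col = ts.column - 1
        for label in list(tips):
            state = ts.states.get(mapping[label], ts.default_state)
            s = tips[label]
            tips[label] = s[:col] + state + s[col + 1 :]
        if ts.root_state:
            root_seq = root_seq[:col] + ts.root_state + root_seq[col + 1 :]

    records = [
        SequenceRecord(
            id=label, residues=tips[label], species=mapping[label]
        )
        for label in gene_tree.leaf_labels()
    ]
    return SimulatedFamily(
        alignment=Alignment(records),
        true_gene_tree=gene_tree,
        events=events,
        true_root_sequence=root_seq,
        tip_mapping=mapping,
        seed=spec.seed,
    )


# --------------------------------------------------------------------------
# biophysics presets
# --------------------------------------------------------------------------

# Equilibrium presets: two-state parameters (kcal/mol, kcal/mol/M) and
# far-UV ellipticity baselines (deg cm^2/dmol at 215 nm).
EQUILIBRIUM_PRESETS: dict[str, dict] = {
    # wild type: Cm = 7.6/4.0 = 1.9 M
    "wt_equilibrium": dict(
        dG=7.6, m=4.0, yN=-4500.0, mN=60.0, yU=-1500.0, mU=-40.0,
        temperature=293.15,
    ),
    # Trp95Leu variant: Cm = 6.6/4.0 = 1.65 M; 1.0 kcal/mol less stable
    "w95l_equilibrium": dict(
        dG=6.6, m=4.0, yN=-4400.0, mN=60.0, yU=-1500.0, mU=-40.0,
        temperature=293.15,
    ),
}

# Kinetic presets: single-exponential rate (1/s), amplitude and offset
# (ellipticity), instrument dead time, and a sampling window matched to the
# phase (stopped-flow at 215 nm for the fast phases, conventional CD at
# 263 nm for the slow one).
TRACE_PRESETS: dict[str, dict] = {
    "fold_fast": dict(
        k=1.65, amplitude=2000.0, offset=-4400.0,
        dead_time=0.005, duration=10.0, step=0.001, wavelength=215.0,
    ),
    "fold_slow": dict(
        k=0.003, amplitude=60.0, offset=-150.0,
        dead_time=0.0, duration=1500.0, step=1.0, wavelength=263.0,
    ),
    "unfold_wt": dict(
        k=0.22, amplitude=-2400.0, offset=-1800.0,
        dead_time=0.005, duration=20.0, step=0.01, wavelength=215.0,
    ),
    "unfold_w95l": dict(
        k=0.4, amplitude=-2400.0, offset=-1800.0,
        dead_time=0.005, duration=20.0, step=0.01, wavelength=215.0,
    ),
}


@dataclass
class CurveSimSpec:
    """True equilibrium parameters plus sampling grid and noise level."""

    dG: float
    m: float
    yN: float
    mN: float
    yU: float
    mU: float
    temperature: float = 293.15
    d_max: float = 4.0
    n_points: int = 41
    noise_frac: float = 0.02  # sigma as a fraction of the model signal span
    seed: int = 0

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, **overrides) -> "CurveSimSpec":
        if name not in EQUILIBRIUM_PRESETS:
            raise KeyError(f"unknown equilibrium preset {name!r}")
        return cls(**{**EQUILIBRIUM_PRESETS[name], **overrides}, seed=seed)

    @property
    def Cm(self) -> float:
        return self.dG / self.m


@dataclass
class TraceSimSpec:
    """True kinetic parameters plus sampling window and noise level."""

    k: float
    amplitude: float
    offset: float
    duration: float
    step: float
    dead_time: float = 0.0
    wavelength: float | None = None
    snr: float = 20.0  # |amplitude| / sigma
    seed: int = 0

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, **overrides) -> "TraceSimSpec":
        if name not in TRACE_PRESETS:
            raise KeyError(f"unknown trace preset {name!r}")
        return cls(**{**TRACE_PRESETS[name], **overrides}, seed=seed)


def simulate_denaturation(spec: CurveSimSpec) -> DenaturationCurve:
    """Model curve on an even 0..d_max grid plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    D = np.linspace(0.0, spec.d_max, spec.n_points)
    y = santoro_bolen_signal(
        D, spec.dG, spec.m, spec.yN, spec.mN, spec.yU, spec.mU,
        spec.temperature,
    )
    sigma = spec.noise_frac * float(np.ptp(y))
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(D))
    return DenaturationCurve(D, y, temperature=spec.temperature)


def simulate_trace(spec: TraceSimSpec) -> KineticTrace:
    """Exponential decay on an even time grid plus Gaussian noise.

    The grid starts at one step (time zero itself is never observed); points
    before the dead time are kept in the trace but flagged for exclusion via
    ``KineticTrace.dead_time``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.step, spec.duration + spec.step / 2, spec.step)
    y = spec.offset + spec.amplitude * np.exp(-spec.k * t)
    sigma = abs(spec.amplitude) / spec.snr if spec.snr > 0 else 0.0
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(t))
    return KineticTrace(
        t, y, dead_time=spec.dead_time, wavelength=spec.wavelength
    )
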