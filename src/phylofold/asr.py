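"""Ancestral sequence reconstruction under a reversible model with
discrete-gamma rate variation.

Likelihoods are computed by Felsenstein's pruning algorithm with per-node
scaling for underflow control.  Rate variation among sites uses the usual
k-category discretization of a mean-one gamma distribution (equal category
probabilities, each category represented by its conditional mean).

Two reconstructions are provided:

* **marginal** — per internal node and site, the posterior distribution over
  the 20 states given all tip data, computed by an up-down (inside-outside)
  pass and mixed over rate categories with their posterior weights;
* **joint** — the single most probable simultaneous assignment of states to
  all internal nodes (Pupko-style max-product dynamic programming), taking
  the best rate category per site.

Branch lengths are taken from the input tree as given; gaps and unknown
residues are treated as missing data (all-ones partials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .family_io import Alignment, GAP
from .substmodel import SubstitutionModel
from .treeutils import Node, PhyloTree

__all__ = [
    "GammaRates",
    "AncestralReconstruction",
    "discretize_gamma",
    "site_log_likelihood",
    "marginal_asr",
    "joint_asr",
]


@dataclass(frozen=True)
class GammaRates:
    """Equal-probability discrete-gamma rate categories with unit mean."""

    alpha: float
    k: int
    rates: tuple[float, ...]

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple([1.0 / self.k] * self.k)


def discretize_gamma(alpha: float, k: int) -> GammaRates:
    """k equal-probability categories, each represented by its mean rate.

    Category boundaries are gamma(alpha, 1/alpha) quantiles at i/k; the mean
    of category i follows from the incomplete-gamma identity
    E[X | a < X < b] = [F_{alpha+1}(b) - F_{alpha+1}(a)] / (1/k) for a
    mean-one gamma.  Rates are renormalized so they average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return GammaRates(alpha=alpha, k=1, rates=(1.0,))
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # F_{alpha+1}(x) with scale 1/alpha is gammainc(alpha+1, alpha*x)
    cdf_hi = np.where(np.isinf(upper), 1.0, gammainc(alpha + 1, alpha * upper))
    cdf_lo = gammainc(alpha + 1, alpha * lower)
    rates = k * (cdf_hi - cdf_lo)
    rates = rates / rates.mean()
    return GammaRates(alpha=alpha, k=k, rates=tuple(float(r) for r in rates))


@dataclass
class AncestralReconstruction:
    """Marginal posteriors and/or joint states per internal node and site."""

    node_names: list[str]
    n_sites: int
    states: str
    marginals: dict[str, np.ndarray] | None = None  # name -> (n_sites, 20)
    joint_states: dict[str, str] | None = None  # name -> sequence
    joint_log_likelihood: float | None = None
    site_log_likelihoods: np.ndarray | None = None

    def marginal_mode(self, name: str, site: int) -> tuple[str, float]:
        """(state, posterior probability) of the marginal mode; site 1-based."""
        p = self.marginals[name][site - 1]
        i = int(np.argmax(p))
        return self.states[i], float(p[i])


def _name_internal_nodes(tree: PhyloTree) -> list[str]:
    """Assign stable names N1.. (preorder) to unnamed internal nodes."""
    names = []
    i = 0
    for node in tree.preorder():
        if node.is_leaf:
            continue
        if not getattr(node, "asr_name", None):
            i += 1
            node.asr_name = node.label if node.label else f"N{i}"
        names.append(node.asr_name)
    return names


def _tip_partial(model: SubstitutionModel, symbol: str) -> np.ndarray:
    if symbol in (GAP, "X"):
        return np.ones(len(model.pi))
    v = np.zeros(len(model.pi))
    v[model.state_index(symbol)] = 1.0
    return v


def _edge_matrices(
    tree: PhyloTree, model: SubstitutionModel, rate: float
) -> dict[int, np.ndarray]:
    return {
        id(n): model.transition_matrix((n.length or 0.0) * rate)
        for n in tree.postorder()
        if n.parent is not None
    }


def _inside(
    tree: PhyloTree,
    tip_states: dict[str, str],
    model: SubstitutionModel,
    P: dict[int, np.ndarray],
) -> tuple[dict[int, np.ndarray], float]:
    """Scaled pruning partials; returns (partials, total log scale)."""
    partial: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            partial[id(node)] = _tip_partial(model, tip_states[node.label])
            continue
        v = np.ones(len(model.pi))
        for c in node.children:
            v = v * (P[id(c)] @ partial[id(c)])
        s = v.max()
        if s <= 0:
            raise FloatingPointError("zero likelihood during pruning")
        partial[id(node)] = v / s
        log_scale += np.log(s)
    return partial, log_scale


def _category_log_likelihoods(
    tree: PhyloTree,
    tip_states: dict[str, str],
    model: SubstitutionModel,
    gamma: GammaRates,
):
    """Per-category log-likelihood of one site, plus the inside passes."""
    out = []
    for rate in gamma.rates:
        P = _edge_matrices(tree, model, rate)
        partial, log_scale = _inside(tree, tip_states, model, P)
        ll = np.log(float(model.pi @ partial[id(tree.root)])) + log_scale
        out.append((ll, P, partial))
    return out


def site_log_likelihood(
    tree: PhyloTree,
    tip_states: dict[str, str],
    model: SubstitutionModel,
    gamma: GammaRates | None = None,
) -> float:
    """log P(site data | tree, model) mixed over gamma categories."""
    gamma = gamma or discretize_gamma(1.0, 1)
    cat = _category_log_likelihoods(tree, tip_states, model, gamma)
    lls = np.array([c[0] for c in cat])
    m = lls.max()
    return float(m + np.log(np.mean(np.exp(lls - m))))


def _outside(
    tree: PhyloTree,
    model: SubstitutionModel,
    P: dict[int, np.ndarray],
    partial: dict[int, np.ndarray],
) -> dict[int, np.ndarray]:
    """Outside messages: for each node v, O_v(s) proportional to the
    likelihood of data outside v's subtree given state s at v (root prior
    included).  Each vector is rescaled by its max to avoid underflow."""
    out: dict[int, np.ndarray] = {id(tree.root): model.pi.copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        base = out[id(node)]
        down = {id(c): P[id(c)] @ partial[id(c)] for c in node.children}
        for c in node.children:
            sib = base.copy()
            for c2 in node.children:
                if c2 is not c:
                    sib = sib * down[id(c2)]
            o = P[id(c)].T @ sib  # sum over parent states
            s = o.max()
            out[id(c)] = o / (s if s > 0 else 1.0)
    return out


def marginal_asr(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    gamma: GammaRates | None = None,
) -> AncestralReconstruction:
    """Marginal posterior state distributions at every internal node.

    Posteriors are mixed over rate categories with the per-site category
    posterior weights; root marginals use the stationary frequencies as
    prior.
    """
    gamma = gamma or discretize_gamma(1.0, 1)
    tree = tree.copy()
    names = _name_internal_nodes(tree)
    internal = [n for n in tree.preorder() if not n.is_leaf]
    n_sites = aln.n_columns
    marg = {nm: np.zeros((n_sites, len(model.pi))) for nm in names}
    site_ll = np.zeros(n_sites)

    for s in range(1, n_sites + 1):
        tip_states = {r.id: r.residues[s - 1] for r in aln.records}
        cat = _category_log_likelihoods(tree, tip_states, model, gamma)
        lls = np.array([c[0] for c in cat])
        m = lls.max()
        w = np.exp(lls - m)
        w = w / w.sum()  # category posterior (uniform prior)
        site_ll[s - 1] = m + np.log(np.mean(np.exp(lls - m)))
        for (ll, P, partial), wk in zip(cat, w):
            outside = _outside(tree, model, P, partial)
            for node in internal:
                post = outside[id(node)] * partial[id(node)]
                post = post / post.sum()
                marg[node.asr_name][s - 1] += wk * post

    return AncestralReconstruction(
        node_names=names,
        n_sites=n_sites,
        states=model.states,
        marginals=marg,
        site_log_likelihoods=site_ll,
    )


def joint_asr(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    gamma: GammaRates | None = None,
) -> AncestralReconstruction:
    """Most probable joint assignment of internal states (per site).

    Max-product dynamic programming over internal states, run per rate
    category; the category achieving the best joint probability (weights
    are uniform, so the max decides) supplies the assignment.
    """
    gamma = gamma or discretize_gamma(1.0, 1)
    tree = tree.copy()
    names = _name_internal_nodes(tree)
    internal = [n for n in tree.preorder() if not n.is_leaf]
    n_states = len(model.pi)
    n_sites = aln.n_columns
    joint = {nm: [] for nm in names}
    total_ll = 0.0
    log_pi = np.log(model.pi)

    for s in range(1, n_sites + 1):
        tip_states = {r.id: r.residues[s - 1] for r in aln.records}
        best_ll = -np.inf
        best_assign: dict[str, int] = {}
        for rate, weight in zip(gamma.rates, gamma.weights):
            P = _edge_matrices(tree, model, rate)
            logP = {k: np.log(np.maximum(v, 1e-300)) for k, v in P.items()}
            # L[node][parent_state] = best log-prob of node's subtree given
            # the parent's state, maximizing over the node's own state
            L: dict[int, np.ndarray] = {}
            back: dict[int, np.ndarray] = {}
            for node in tree.postorder():
                if node is tree.root:
                    continue
                if node.is_leaf:
                    sym = tip_states[node.label]
                    if sym in (GAP, "X"):
                        # missing tip data marginalizes out: factor 1
                        L[id(node)] = np.zeros(n_states)
                    else:
                        L[id(node)] = logP[id(node)][:, model.state_index(sym)]
                    continue
                child_sum = np.zeros((n_states,))
                for c in node.children:
                    child_sum = child_sum + L[id(c)]
                score = logP[id(node)] + child_sum[None, :]
                L[id(node)] = score.max(axis=1)
                back[id(node)] = score.argmax(axis=1)
            root = tree.root
            root_score = log_pi.copy()
            for c in root.children:
                root_score = root_score + L[id(c)]
            ll = float(root_score.max()) + np.log(weight)
            if ll > best_ll:
                best_ll = ll
                assign: dict[int, int] = {id(root): int(root_score.argmax())}
                for node in tree.preorder():
                    if node.is_leaf or node is tree.root:
                        continue
                    assign[id(node)] = int(back[id(node)][assign[id(node.parent)]])
                best_assign = {
                    n.asr_name: assign[id(n)] for n in internal
                }
        total_ll += best_ll
        for nm in names:
            joint[nm].append(model.states[best_assign[nm]])

    return AncestralReconstruction(
        node_names=names,
        n_sites=n_sites,
        states=model.states,
        joint_states={nm: "".join(seq) for nm, seq in joint.items()},
        joint_log_likelihood=total_ll,
    )


def estimate_alpha(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    k: int = 4,
    bounds: tuple[float, float] = (0.05, 20.0),
) -> float:
    """Maximum-likelihood gamma shape by golden-section search."""
    from scipy.optimize import minimize_scalar

    def neg_ll(alpha: float) -> float:
        g = discretize_gamma(alpha, k)
        return -sum(
            site_log_likelihood(
                tree, {r.id: r.residues[s] for r in aln.records}, model, g
            )
            for s in range(aln.n_columns)
        )

    res = minimize_scalar(neg_ll, bounds=bounds, method="bounded")
    return float(res.x)
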