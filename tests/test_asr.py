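import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from phylofold.asr import (
    discretize_gamma,
    joint_asr,
    marginal_asr,
    site_log_likelihood,
)
from phylofold.family_io import Alignment, SequenceRecord
from phylofold.phylo_build import reroot
from phylofold.synthetic_data import (
    FamilySimSpec,
    TrackedSite,
    simulate_family,
)
from phylofold.treeutils import PhyloTree


def quadrature_category_means(alpha, k):
    """Oracle: category means of the mean-one gamma by numerical integration."""
    bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    bounds[-1] = np.inf
    means = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(
            lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1.0 / alpha),
            lo,
            min(hi, 1e3),
        )
        means.append(val * k)  # each category has probability 1/k
    return np.array(means)


def quartet_brute_force(tree, states, model, gamma):
    """Exhaustive enumeration over all internal-state assignments of a
    rooted 4-tip balanced tree, per rate category."""
    root = tree.root
    left, right = root.children
    tips = {n.label: n for n in tree.root.leaves()}
    idx = {lbl: model.state_index(s) for lbl, s in states.items()}
    per_cat = []
    for rate in gamma.rates:
        P = {
            lbl: model.transition_matrix((tips[lbl].length or 0) * rate)
            for lbl in tips
        }
        Pl = model.transition_matrix((left.length or 0) * rate)
        Pr = model.transition_matrix((right.length or 0) * rate)
        lt = [l.label for l in left.leaves()]
        rt = [l.label for l in right.leaves()]
        total = 0.0
        post_root = np.zeros(20)
        best = (-np.inf, None)
        for r, x, y in itertools.product(range(20), repeat=3):
            p = model.pi[r] * Pl[r, x] * Pr[r, y]
            for lbl in lt:
                p *= P[lbl][x, idx[lbl]]
            for lbl in rt:
                p *= P[lbl][y, idx[lbl]]
            total += p
            post_root[r] += p
            if p > best[0]:
                best = (p, (r, x, y))
        per_cat.append((total, post_root, best))
    return per_cat


class TestDiscretizeGamma:
    def test_single_category_is_unit_rate(self):
        g = discretize_gamma(0.5, 1)
        assert g.rates == (1.0,)

    def test_large_alpha_limit(self):
        g = discretize_gamma(1e8, 4)
        assert np.allclose(g.rates, 1.0, atol=1e-3)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 1.0, 2.0])
    def test_matches_quadrature_oracle(self, alpha):
        g = discretize_gamma(alpha, 4)
        assert np.allclose(g.rates, quadrature_category_means(alpha, 4), atol=1e-6)

    def test_mean_is_one(self):
        for alpha in (0.1, 0.7, 5.0):
            g = discretize_gamma(alpha, 8)
            assert np.dot(g.rates, g.weights) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)


class TestSiteLikelihood:
    def test_single_tip_zero_branch_is_log_pi(self, model):
        t = PhyloTree.from_newick("(A:0.0);", rooted=True)
        ll = site_log_likelihood(t, {"A": "W"}, model)
        assert ll == pytest.approx(np.log(model.pi[model.state_index("W")]))

    def test_two_identical_tips_zero_branches(self, model):
        t = PhyloTree.from_newick("(A:0.0,B:0.0);", rooted=True)
        ll = site_log_likelihood(t, {"A": "W", "B": "W"}, model)
        assert ll == pytest.approx(np.log(model.pi[model.state_index("W")]))

    def test_matches_exhaustive_enumeration(self, model, quartet_tree):
        states = {"A": "W", "B": "W", "C": "L", "D": "K"}
        gamma = discretize_gamma(0.7, 4)
        per_cat = quartet_brute_force(quartet_tree, states, model, gamma)
        expected = np.log(np.mean([c[0] for c in per_cat]))
        got = site_log_likelihood(quartet_tree, states, model, gamma)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_pulley_principle(self, model, quartet_tree):
        states = {"A": "W", "B": "F", "C": "L", "D": "L"}
        gamma = discretize_gamma(1.0, 4)
        base = site_log_likelihood(quartet_tree, states, model, gamma)
        for tip in "ABCD":
            rerooted = reroot(quartet_tree, tip)
            assert site_log_likelihood(
                rerooted, states, model, gamma
            ) == pytest.approx(base, abs=1e-9)

    def test_gap_is_missing_data(self, model):
        t = PhyloTree.from_newick("(A:0.1,B:0.1);", rooted=True)
        ll_gap = site_log_likelihood(t, {"A": "W", "B": "-"}, model)
        # marginalizing B out leaves the single-tip likelihood
        t1 = PhyloTree.from_newick("(A:0.1);", rooted=True)
        ll_single = site_log_likelihood(t1, {"A": "W"}, model)
        assert ll_gap == pytest.approx(ll_single, abs=1e-9)


def quartet_alignment(states):
    return Alignment(
        [SequenceRecord(id=k, residues=v) for k, v in states.items()]
    )


class TestMarginalAsr:
    def test_zero_branch_identical_tips_point_mass(self, model):
        t = PhyloTree.from_newick("(A:0.0,B:0.0);", rooted=True)
        rec = marginal_asr(t, quartet_alignment({"A": "W", "B": "W"}), model)
        state, p = rec.marginal_mode(rec.node_names[0], 1)
        assert state == "W" and p == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_oracle(self, model, quartet_tree):
        states = {"A": "W", "B": "W", "C": "L", "D": "L"}
        gamma = discretize_gamma(0.7, 4)
        per_cat = quartet_brute_force(quartet_tree, states, model, gamma)
        tot = sum(c[0] for c in per_cat)
        expected = sum(c[1] for c in per_cat) / tot
        rec = marginal_asr(quartet_tree, quartet_alignment(states), model, gamma)
        got = rec.marginals[rec.node_names[0]][0]
        assert np.allclose(got, expected, atol=1e-9)

    def test_posteriors_sum_to_one_everywhere(self, model, quartet_tree):
        states = {"A": "W", "B": "F", "C": "L", "D": "-"}
        rec = marginal_asr(
            quartet_tree, quartet_alignment(states), model,
            discretize_gamma(0.5, 4),
        )
        for name in rec.node_names:
            assert np.allclose(rec.marginals[name].sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_injected_basal_state(self, model, species8):
        fam = simulate_family(
            FamilySimSpec(
                species_tree=species8, seq_length=60, seed=7, alpha=1.0,
                tracked_site=TrackedSite(
                    column=30,
                    states={"RAJEG": "L", "DANRE": "L", "ONCMY": "L"},
                    default_state="W", root_state="L",
                ),
            )
        )
        tree = fam.true_gene_tree
        rec = marginal_asr(
            tree, fam.alignment, model, discretize_gamma(1.0, 4)
        )
        # at the tracked column the basal clade is L; the root posterior
        # should put substantial weight on the injected ancestral state
        state, p = rec.marginal_mode(rec.node_names[0], 30)
        assert state in ("L", "W")
        post_L = rec.marginals[rec.node_names[0]][29][model.state_index("L")]
        assert post_L > 0.3

    def test_root_true_state_recovered_on_simulated_sites(self, model, species8):
        hits = 0
        confident = 0
        fam = simulate_family(
            FamilySimSpec(species_tree=species8, seq_length=300, seed=2)
        )
        rec = marginal_asr(fam.true_gene_tree, fam.alignment, model)
        root = rec.node_names[0]
        for s in range(1, 301):
            state, p = rec.marginal_mode(root, s)
            if p > 0.9:
                confident += 1
                hits += state == fam.true_root_sequence[s - 1]
        assert confident > 50
        assert hits / confident >= 0.9


class TestJointAsr:
    def test_uniform_tips_give_uniform_assignment(self, model, quartet_tree):
        states = {k: "W" for k in "ABCD"}
        rec = joint_asr(quartet_tree, quartet_alignment(states), model)
        assert all(seq == "W" for seq in rec.joint_states.values())

    def test_matches_enumeration_argmax(self, model, quartet_tree):
        states = {"A": "W", "B": "F", "C": "L", "D": "L"}
        gamma = discretize_gamma(0.7, 2)
        per_cat = quartet_brute_force(quartet_tree, states, model, gamma)
        best = max(per_cat, key=lambda c: c[2][0])
        r, x, y = best[2][1]
        rec = joint_asr(quartet_tree, quartet_alignment(states), model, gamma)
        assert rec.joint_states[rec.node_names[0]] == model.states[r]
        assert rec.joint_states[rec.node_names[1]] == model.states[x]
        assert rec.joint_states[rec.node_names[2]] == model.states[y]

    def test_joint_likelihood_below_marginal(self, model, quartet_tree):
        states = {"A": "W", "B": "F", "C": "L", "D": "K"}
        gamma = discretize_gamma(1.0, 4)
        aln = quartet_alignment(states)
        joint = joint_asr(quartet_tree, aln, model, gamma)
        marg = marginal_asr(quartet_tree, aln, model, gamma)
        assert joint.joint_log_likelihood <= marg.site_log_likelihoods.sum() + 1e-12


def test_likelihood_peaks_near_generating_scale(model, species8):
    fam = simulate_family(
        FamilySimSpec(species_tree=species8, seq_length=200, seed=5)
    )
    tree = fam.true_gene_tree

    def total_ll(scale):
        t = tree.copy()
        for n in t.postorder():
            if n.length is not None:
                n.length *= scale
        rec = marginal_asr(t, fam.alignment, model)
        return rec.site_log_likelihoods.sum()

    lls = {s: total_ll(s) for s in (0.25, 1.0, 4.0)}
    assert lls[1.0] > lls[0.25]
    assert lls[1.0] > lls[4.0]
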