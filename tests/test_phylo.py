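import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitosignal import phylo, seqio
from mitosignal.phylo import (
    SubstitutionModel,
    Tree,
    assign_gamma_categories,
    discrete_gamma_rates,
    log_likelihood,
    ml_tree_small,
    same_topology,
    simulate,
    strip_fast_sites,
)


def brute_force_log_likelihood(aln, tree, model):
    """Exhaustive summation over all internal-node state combinations."""
    rates, weights = model.category_rates()
    states = model.states
    n = len(states)
    nodes = tree.postorder()
    internal = [nd for nd in nodes if not nd.is_leaf]
    leaf_state = {
        nd: states.index(aln.sequence(nd.name)[0]) for nd in nodes if nd.is_leaf
    }
    total = 0.0
    per_site = []
    for site in range(aln.n_sites):
        for nd in tree.leaves():
            leaf_state[nd] = states.index(aln.sequence(nd.name)[site])
        lik = 0.0
        for r, w in zip(rates, weights):
            P = {nd: model.transition_matrix(nd.length * r) for nd in nodes if nd.parent}
            cat = 0.0
            for combo in itertools.product(range(n), repeat=len(internal)):
                assign = dict(zip(internal, combo))
                prob = model.freqs[assign[tree.root]]
                for nd in nodes:
                    if nd.parent is None:
                        continue
                    s_parent = assign[nd.parent]
                    s_child = leaf_state[nd] if nd.is_leaf else assign[nd]
                    prob *= P[nd][s_parent, s_child]
                cat += prob
            lik += w * cat
        per_site.append(math.log(lik))
        total += per_site[-1]
    return total, np.array(per_site)


def _random_alignment(rng, taxa, n_sites):
    mat = rng.choice(list("ACGT"), size=(len(taxa), n_sites))
    return seqio.Alignment(list(taxa), mat)


class TestPruningOracle:
    @pytest.mark.parametrize(
        "newick,model",
        [
            ("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.1);", SubstitutionModel.jc69()),
            (
                "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07,E:0.4);",
                SubstitutionModel.hky(3.0, [0.35, 0.15, 0.2, 0.3], 4, 0.5),
            ),
            (
                "(((A:0.02,B:0.9):0.3,C:0.05):0.2,D:0.6,E:0.01);",
                SubstitutionModel.gtr([1, 2, 0.5, 1.5, 4, 1], [0.4, 0.1, 0.2, 0.3], 2, 1.2),
            ),
        ],
    )
    def test_pruning_equals_exhaustive_summation(self, newick, model):
        tree = Tree.from_newick(newick)
        rng = np.random.default_rng(17)
        aln = _random_alignment(rng, tree.leaf_names(), 12)
        total, per_site = log_likelihood(aln, tree, model)
        b_total, b_per_site = brute_force_log_likelihood(aln, tree, model)
        assert total == pytest.approx(b_total, rel=1e-10)
        assert per_site == pytest.approx(b_per_site, rel=1e-10)

    def test_two_taxon_jc_closed_form(self):
        t = 0.37
        tree = Tree.from_newick(f"(A:{t / 2},B:{t / 2});")
        aln = seqio.Alignment(["A", "B"], np.array([list("ACGTA"), list("ACGTT")]))
        total, _ = log_likelihood(aln, tree, SubstitutionModel.jc69())
        p_same = 0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3))
        p_diff = 0.25 * (0.25 - 0.25 * math.exp(-4 * t / 3))
        assert total == pytest.approx(4 * math.log(p_same) + math.log(p_diff), rel=1e-12)

    def test_zero_branch_lengths_identical_sequences(self):
        tree = Tree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = seqio.Alignment(["A", "B", "C", "D"], np.array([list("ACG")] * 4))
        total, per_site = log_likelihood(aln, tree, SubstitutionModel.jc69())
        assert per_site == pytest.approx(np.full(3, math.log(0.25)))

    def test_invariant_to_rerooting_and_taxon_order(self):
        model = SubstitutionModel.hky(2.5, [0.3, 0.2, 0.2, 0.3], 4, 0.7)
        rng = np.random.default_rng(3)
        aln = _random_alignment(rng, ["A", "B", "C", "D"], 30)
        t1 = Tree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.1);")
        # same unrooted tree with the root moved along the internal edge
        t2 = Tree.from_newick("((B:0.2,A:0.1):0.075,(C:0.3,D:0.15):0.075);")
        l1, _ = log_likelihood(aln, t1, model)
        l2, _ = log_likelihood(aln, t2, model)
        assert l1 == pytest.approx(l2, rel=1e-9)
        shuffled = aln.subset_taxa(["D", "B", "A", "C"])
        l3, _ = log_likelihood(shuffled, t1, model)
        assert l1 == pytest.approx(l3, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(alpha=st.floats(0.06, 40.0), k=st.integers(2, 8))
def test_discrete_gamma_mean_is_one(alpha, k):
    rates, weights = discrete_gamma_rates(alpha, k)
    assert float(rates @ weights) == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(rates) > 0)


class TestFitAndSimulate:
    def test_branch_length_recovery_two_taxa(self):
        tree = Tree.from_newick("(A:0.05,B:0.05);")
        sim = simulate(tree, SubstitutionModel.jc69(), 20000, seed=5)
        fit = phylo.fit_model(sim, tree, family="jc69", n_categories=1, max_sweeps=5)
        t_hat = sum(nd.length for nd in fit.tree.branches())
        # JC variance of d-hat at p = 3/4(1-e^{-4t/3}):
        t_true = 0.1
        p = 0.75 * (1 - math.exp(-4 * t_true / 3))
        var = p * (1 - p) / 20000 / (1 - 4 * p / 3) ** 2
        assert abs(t_hat - t_true) < 3 * math.sqrt(var)

    def test_gamma_shape_recovery(self):
        tree = Tree.from_newick(
            "(((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1):0.1,(E:0.2,F:0.2):0.1);"
        )
        model = SubstitutionModel.hky(3.0, [0.3, 0.2, 0.2, 0.3], 4, 0.5)
        sim = simulate(tree, model, 6000, seed=11)
        fit = phylo.fit_model(sim, tree, family="hky", n_categories=4, max_sweeps=3)
        assert fit.model.gamma_shape == pytest.approx(0.5, rel=0.25)

    def test_constant_alignment_drives_lengths_to_bound(self):
        aln = seqio.Alignment(["A", "B", "C"], np.array([list("AAAA")] * 3))
        tree = Tree.from_newick("(A:0.1,B:0.1,C:0.1);")
        fit = phylo.fit_model(aln, tree, family="jc69", n_categories=1, max_sweeps=2)
        # bounded 1-D search stops within xatol of the 1e-8 lower bound
        assert all(nd.length < 1e-4 for nd in fit.tree.branches())

    def test_simulated_composition_near_stationary(self):
        freqs = np.array([0.4, 0.1, 0.2, 0.3])
        model = SubstitutionModel.gtr(np.ones(6), freqs)
        tree = Tree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        sim = simulate(tree, model, 20000, seed=2)
        counts = phylo.empirical_freqs(sim, pseudocount=0)
        assert counts == pytest.approx(freqs, abs=0.01)

    def test_at_override_shifts_one_taxon(self):
        model = SubstitutionModel.hky(2.0, [0.3, 0.2, 0.2, 0.3])
        tree = Tree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:1.2):0.1);")
        rich = np.array([0.45, 0.05, 0.05, 0.45])
        sim = simulate(
            tree, model, 10000, seed=4, branch_freq_overrides={"D": rich}
        )
        at = {
            t: np.isin(sim.row(t), list("AT")).mean() for t in sim.taxon_names
        }
        assert at["D"] - max(at[t] for t in "ABC") > 0.1


class TestGammaAssignment:
    def test_posteriors_sum_to_one_and_monotone_cases(self):
        tree = Tree.from_newick("((A:0.3,B:0.3):0.1,(C:0.3,D:0.3):0.1);")
        model = SubstitutionModel.jc69(4, 0.3)
        # site 1 constant, site 2 all four taxa distinct
        mat = np.array([list("AA"), list("AC"), list("AG"), list("AT")])
        aln = seqio.Alignment(["A", "B", "C", "D"], mat)
        res = assign_gamma_categories(aln, tree, model)
        assert res.posterior.sum(axis=1) == pytest.approx(np.ones(2))
        assert res.category[0] == 0  # constant site in the slowest category
        assert res.category[1] == 3  # maximally variable site in the fastest

    def test_strip_bookkeeping(self):
        tree = Tree.from_newick("((A:0.3,B:0.3):0.1,(C:0.3,D:0.3):0.1);")
        model = SubstitutionModel.jc69(4, 0.3)
        # columns range from constant to fully variable
        mat = np.array([list("AAAA"), list("AACC"), list("AAGG"), list("ACGT")])
        aln = seqio.Alignment(["A", "B", "C", "D"], mat.T)
        res = assign_gamma_categories(aln, tree, model)
        stripped, removed = strip_fast_sites(aln, res)
        n_fast = int((res.category == 3).sum())
        assert stripped.n_sites == aln.n_sites - n_fast
        assert removed == pytest.approx(100 * n_fast / aln.n_sites)

    def test_strip_without_fast_sites_is_identity(self):
        tree = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        model = SubstitutionModel.jc69(4, 0.5)
        aln = seqio.Alignment(["A", "B", "C", "D"], np.array([list("AAAA")] * 4))
        res = assign_gamma_categories(aln, tree, model)
        stripped, removed = strip_fast_sites(aln, res)
        assert removed == 0.0
        assert np.array_equal(stripped.matrix, aln.matrix)


class TestTreeSearch:
    def test_four_taxon_exhaustive_picks_best_quartet(self, jc):
        true = Tree.from_newick("((A:0.15,B:0.15):0.2,(C:0.15,D:0.15):0.2);")
        sim = simulate(true, jc, 2000, seed=9)
        res = ml_tree_small(sim, jc)
        assert res.method == "exhaustive" and res.n_evaluated == 3
        assert same_topology(res.tree, true)

    def test_six_taxon_recovery_rate(self, jc):
        true = Tree.from_newick(
            "(((A:0.15,B:0.15):0.08,(C:0.15,D:0.15):0.08):0.08,(E:0.15,F:0.15):0.08);"
        )
        rng = np.random.default_rng(21)
        hits = 0
        n_rep = 8
        for _ in range(n_rep):
            sim = simulate(true, jc, 1000, seed=rng)
            res = ml_tree_small(sim, jc)
            hits += same_topology(res.tree, true)
        assert hits >= 7

    def test_exhaustive_and_nni_agree(self, jc):
        true = Tree.from_newick(
            "(((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1):0.1,(E:0.15,F:0.15):0.1);"
        )
        sim = simulate(true, jc, 800, seed=33)
        exh = ml_tree_small(sim, jc, max_exhaustive=6)
        nni = ml_tree_small(sim, jc, max_exhaustive=5, seed=1)
        assert exh.method == "exhaustive" and nni.method == "nni"
        assert same_topology(exh.tree, nni.tree)

    def test_topology_enumeration_count(self):
        assert len(phylo.enumerate_topologies(list("ABCD"))) == 3
        assert len(phylo.enumerate_topologies(list("ABCDE"))) == 15
        assert len(phylo.enumerate_topologies(list("ABCDEF"))) == 105
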