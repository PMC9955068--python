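import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitosignal import fclm, phylo
from mitosignal.fclm import (
    ClusterAssignment,
    classify_region,
    enumerate_quartets,
    quartet_weights,
)


def _clusters(sizes):
    taxa = {}
    k = 0
    for cid, n in zip((1, 2, 3, 4), sizes):
        taxa[cid] = [f"c{cid}t{i}" for i in range(n)]
        k += n
    return ClusterAssignment(taxa)


class TestEnumerateQuartets:
    def test_small_product(self):
        qs = enumerate_quartets(_clusters([2, 1, 1, 3]), cap=None)
        assert len(qs) == 6
        assert len(set(qs)) == 6

    def test_published_cluster_sizes_product(self):
        qs = enumerate_quartets(_clusters([22, 3, 1, 5]), cap=None)
        assert len(qs) == 330

    def test_cap_subsamples_reproducibly(self):
        c = _clusters([22, 3, 1, 5])
        a = enumerate_quartets(c, cap=100, seed=7)
        b = enumerate_quartets(c, cap=100, seed=7)
        assert len(a) == 100 and len(set(a)) == 100
        assert a == b
        assert enumerate_quartets(c, cap=100, seed=8) != a

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ClusterAssignment({1: ["a"], 2: [], 3: ["b"], 4: ["c"]})

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError):
            ClusterAssignment({1: ["a"], 2: ["a"], 3: ["b"], 4: ["c"]})


class TestQuartetWeights:
    def test_equal_loglikelihoods(self):
        assert quartet_weights(-5.0, -5.0, -5.0) == pytest.approx((1 / 3,) * 3)

    def test_softmax_arithmetic(self):
        w = quartet_weights(-100.0, -110.0, -120.0)
        z = np.exp([-100.0, -110.0, -120.0])
        assert w == pytest.approx(tuple(z / z.sum()))
        assert w[0] == pytest.approx(0.9999546, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        l1=st.floats(-1e4, 0),
        l2=st.floats(-1e4, 0),
        l3=st.floats(-1e4, 0),
        c=st.floats(-1e3, 1e3),
    )
    def test_shift_invariance_and_normalisation(self, l1, l2, l3, c):
        w = quartet_weights(l1, l2, l3)
        w_shift = quartet_weights(l1 + c, l2 + c, l3 + c)
        assert sum(w) == pytest.approx(1.0)
        assert w == pytest.approx(w_shift, abs=1e-9)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "w,expected",
        [
            ((1.0, 0.0, 0.0), "corner1"),
            ((0.0, 1.0, 0.0), "corner2"),
            ((0.0, 0.0, 1.0), "corner3"),
            ((1 / 3, 1 / 3, 1 / 3), "center"),
            ((0.5, 0.5, 0.0), "edge12"),
            ((0.5, 0.0, 0.5), "edge13"),
            ((0.0, 0.5, 0.5), "edge23"),
            ((2 / 3, 1 / 3, 0.0), "edge12"),  # corner boundary is exclusive
            ((0.7, 0.2, 0.1), "corner1"),
            ((0.45, 0.35, 0.2), "center"),  # max < 1/2, all diffs < 1/3
            ((0.48, 0.42, 0.10), "edge12"),  # max < 1/2 but spread > 1/3
            ((0.4, 0.35, 0.25), "center"),
        ],
    )
    def test_boundary_cases(self, w, expected):
        assert classify_region(*w) == expected

    def test_permutation_equivariance(self):
        w = (0.55, 0.3, 0.15)
        base = classify_region(*w)
        assert base == "edge12"
        for perm in itertools.permutations(range(3)):
            wp = tuple(w[i] for i in perm)
            region = classify_region(*wp)
            if region.startswith("edge"):
                pair = {perm.index(0) + 1, perm.index(1) + 1}
                assert set(map(int, region[4:])) == pair


class TestRunFclm:
    @pytest.fixture(scope="class")
    def resolved_data(self):
        model = phylo.SubstitutionModel.hky(3.0, [0.3, 0.2, 0.2, 0.3], 4, 0.8)
        tree = phylo.Tree.from_newick(
            "((A1:0.1,A2:0.1):0.05,(B1:0.1,B2:0.1):0.05,"
            "((C1:0.1,C2:0.1):0.05,(D1:0.1,D2:0.1):0.35):0.3);"
        )
        aln = phylo.simulate(tree, model, 800, seed=5)
        clusters = ClusterAssignment(
            {1: ["A1", "A2"], 2: ["B1", "B2"], 3: ["C1", "C2"], 4: ["D1", "D2"]}
        )
        return aln, clusters, model

    def test_resolved_internal_branch_fills_true_corner(self, resolved_data):
        aln, clusters, model = resolved_data
        summary, table = fclm.run_fclm(
            aln, clusters, model, cap=None, seed=0, preferred="12|34"
        )
        assert summary.n_quartets == 16
        assert summary.region_percentages["corner1"] >= 95.0
        assert summary.percent_preferred_corner == summary.region_percentages["corner1"]
        assert sum(summary.region_percentages.values()) == pytest.approx(100.0)

    def test_single_taxon_clusters_single_quartet(self, resolved_data):
        aln, _, model = resolved_data
        clusters = ClusterAssignment({1: ["A1"], 2: ["B1"], 3: ["C1"], 4: ["D1"]})
        summary, table = fclm.run_fclm(aln, clusters, model, cap=None, seed=0)
        assert summary.n_quartets == 1
        assert max(summary.region_percentages.values()) == 100.0

    def test_star_tree_mostly_unresolved(self):
        model = phylo.SubstitutionModel.jc69()
        tree = phylo.Tree.from_newick("(A:0.2,B:0.2,C:0.2,D:0.2);")
        aln = phylo.simulate(tree, model, 600, seed=11)
        clusters = ClusterAssignment({1: ["A"], 2: ["B"], 3: ["C"], 4: ["D"]})
        summary, _ = fclm.run_fclm(aln, clusters, model, cap=None, seed=0)
        corners = sum(summary.region_percentages[f"corner{i}"] for i in (1, 2, 3))
        assert corners <= summary.region_percentages["center"] + sum(
            summary.region_percentages[e] for e in ("edge12", "edge13", "edge23")
        )

    def test_shared_composition_bias_pulls_biased_pair_corner(self):
        """Convergent AT bias in two unrelated clusters inflates their corner."""
        from mitosignal import synthetic

        def corner2_pct(heterogeneous):
            cfg = synthetic.make_branchiopod_scenario(seed=2, heterogeneous=False)
            if heterogeneous:
                # unrelated lineages L1 (cluster 3) and A-clade (cluster 1)
                cfg.at_targets = {"L1": 0.8, "A1": 0.8, "A2": 0.8}
            aln, _ = synthetic.generate(cfg)
            sub = aln.take_columns(np.arange(2000))
            clusters = ClusterAssignment(
                {1: ["A1", "A2"], 2: ["N1", "N2"], 3: ["L1"], 4: ["S1", "S2", "C1", "C2"]}
            )
            model = phylo.fit_model(
                aln, phylo.Tree.from_newick(synthetic.SCENARIO_NEWICK),
                family="gtr", n_categories=4, max_sweeps=1, branch_xatol=1e-3,
            ).model
            summary, _ = fclm.run_fclm(sub, clusters, model, cap=8, seed=4)
            # corner2 pairs cluster1 with cluster3: the biased, unrelated pair
            return summary.region_percentages["corner2"]

        assert corner2_pct(True) > corner2_pct(False)
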