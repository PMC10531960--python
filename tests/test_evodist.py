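import numpy as np
import pytest
from scipy.linalg import expm

import dendropy

from hemiopsin import evodist, simdata
from hemiopsin.evodist import (
    DistanceEstimate,
    discrete_gamma,
    distance_matrix,
    mean_clade_divergence,
    neighbor_joining,
    pair_log_likelihood,
    pairwise_ml_distance,
    transition_probabilities,
    _pair_counts,
)


class TestModel:
    def test_stationarity(self, jtt):
        assert abs(jtt.frequencies.sum() - 1) < 1e-12
        assert np.abs(jtt.frequencies @ jtt.rate_matrix).max() < 1e-12

    def test_spectral_matches_expm(self, jtt):
        for t in (0.01, 0.3, 2.0):
            assert np.abs(
                jtt.transition_matrix(t) - expm(jtt.rate_matrix * t)
            ).max() < 1e-10

    def test_negative_branch_rejected(self, jtt):
        with pytest.raises(ValueError):
            transition_probabilities(jtt, -0.1)


class TestGamma:
    def test_category_means_alpha_one(self):
        # standard 4-category equal-probability discretization at a=1
        g = discrete_gamma(1.0, 4)
        assert np.allclose(g.rates, [0.1370, 0.4768, 1.0000, 2.3863], atol=5e-4)
        assert abs(g.rates.mean() - 1) < 1e-12

    def test_mean_one_any_shape(self):
        for a in (0.2, 0.5, 2.0, 10.0):
            assert abs(discrete_gamma(a, 4).rates.mean() - 1) < 1e-12

    def test_large_alpha_approaches_equal_rates(self, jtt):
        rng = np.random.default_rng(11)
        sc = simdata.SimulationScenario(
            tree="(A:0.2,B:0.2)R;", model=jtt,
            gamma=discrete_gamma(1.0, 4), length=400, seed=5,
        )
        aln, _ = simdata.simulate_alignment(sc)
        d_hi = pairwise_ml_distance(
            aln.sequence("A"), aln.sequence("B"), jtt, discrete_gamma(100.0, 4)
        ).distance
        d_eq = pairwise_ml_distance(
            aln.sequence("A"), aln.sequence("B"), jtt, discrete_gamma(1.0, 1)
        ).distance
        assert abs(d_hi - d_eq) / d_eq < 0.01


class TestPairwiseDistance:
    def test_identical_sequences(self, jtt, gamma1):
        est = pairwise_ml_distance("MKVLW" * 10, "MKVLW" * 10, jtt, gamma1)
        assert est.distance == 0.0 and est.status == "identical"

    def test_symmetry(self, jtt, gamma1):
        a, b = "MKVLWRNDCQEGHILKMFPS", "MRVLWKNDCQEAHILRMFPT"
        da = pairwise_ml_distance(a, b, jtt, gamma1).distance
        db = pairwise_ml_distance(b, a, jtt, gamma1).distance
        assert abs(da - db) < 1e-9

    def test_pairwise_deletion(self, jtt, gamma1):
        est = pairwise_ml_distance("MKV-X", "M-VLW", jtt, gamma1)
        assert est.n_sites == 2  # only columns 1 and 3 comparable

    def test_no_comparable_sites(self, jtt, gamma1):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_ml_distance("--X", "M--", jtt, gamma1)

    def test_matches_grid_search_oracle(self, jtt, gamma1):
        """ML optimum agrees with an independent expm-based grid scan."""
        sc = simdata.SimulationScenario(
            tree="(A:0.25,B:0.25)R;", model=jtt, gamma=gamma1, length=200, seed=3,
        )
        aln, _ = simdata.simulate_alignment(sc)
        counts = _pair_counts(aln.sequence("A"), aln.sequence("B"))
        grid = np.arange(1e-3, 2.0, 1e-3)
        pi = jtt.frequencies

        def oracle_ll(d):
            mix = sum(expm(jtt.rate_matrix * d * r) for r in gamma1.rates) / 4
            return (counts * np.log(pi[:, None] * mix + 1e-300)).sum()

        best = grid[np.argmax([oracle_ll(d) for d in grid])]
        est = pairwise_ml_distance(aln.sequence("A"), aln.sequence("B"), jtt, gamma1)
        assert abs(est.distance - best) <= 1e-3 + 1e-6


class TestDistanceMatrix:
    def test_identical_pair(self, jtt, gamma1):
        from hemiopsin.seqio import Alignment

        aln = Alignment((("a", "MKVLW"), ("b", "MKVLW")))
        D, labels, flags = distance_matrix(aln, jtt, gamma1)
        assert np.allclose(D, 0) and not flags

    def test_symmetric_zero_diagonal(self, jtt, gamma1):
        sc = simdata.SimulationScenario(
            tree="((A:0.1,B:0.1)N:0.1,C:0.2)R;", model=jtt, gamma=gamma1,
            length=150, seed=9,
        )
        aln, _ = simdata.simulate_alignment(sc)
        D, labels, _ = distance_matrix(aln, jtt, gamma1)
        assert np.allclose(D, D.T, atol=1e-9)
        assert np.allclose(np.diag(D), 0)


class TestCladeDivergence:
    def test_disjointness_required(self, jtt, gamma1):
        from hemiopsin.seqio import Alignment

        aln = Alignment((("a", "MKV"), ("b", "MRV")))
        with pytest.raises(ValueError):
            mean_clade_divergence(aln, ["a"], ["a"], jtt, gamma1, bootstrap_reps=0)

    def test_mean_of_equal_distances(self, jtt, gamma1):
        from hemiopsin.seqio import Alignment

        # b and c identical, so both pair distances from a are equal
        aln = Alignment((("a", "MKVLWRND" * 5), ("b", "MRVLWKND" * 5),
                         ("c", "MRVLWKND" * 5)))
        d_ab = pairwise_ml_distance(aln.sequence("a"), aln.sequence("b"),
                                    jtt, gamma1).distance
        summary = mean_clade_divergence(
            aln, ["a"], ["b", "c"], jtt, gamma1, bootstrap_reps=20, seed=1
        )
        assert summary.n_pairs == 2
        assert abs(summary.mean - d_ab) < 1e-9
        assert summary.se > 0  # resampling contributes spread


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d_ab=3, d_ac=4, d_bc=5 -> tip branches (1, 2, 3)
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        nwk = neighbor_joining(D, ["a", "b", "c"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)); path distances are additive
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        labels = ["A", "B", "C", "D"]
        nwk = neighbor_joining(D, labels)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.encode_bipartitions()
        splits = {
            frozenset(lf.taxon.label for lf in e.head_node.leaf_iter())
            for e in tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        }
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits
        assert tree.length() == pytest.approx(15.0)

    def test_nan_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="NaN"):
            neighbor_joining(D, ["a", "b", "c"])

    def test_ultrametric_topology_recovered(self, jtt, gamma1):
        """NJ on true path distances of a pectinate ultrametric tree."""
        nwk = simdata._pectinate_ultrametric(["A", "B", "C", "D", "E"], 0.05)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        D = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
        out = dendropy.Tree.get(
            data=neighbor_joining(D, [t.label for t in taxa]), schema="newick"
        )
        # deepest split of the pectinate tree: {A,B} vs rest
        splits = {
            frozenset(lf.taxon.label for lf in e.head_node.leaf_iter())
            for e in out.preorder_edge_iter()
            if e.head_node.parent_node is not None
        }
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D", "E"}) in splits
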