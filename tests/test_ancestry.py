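"""Ancestral reconstruction, two-state SCS model, stochastic mapping."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from karyorates import (
    ChromosomeModel,
    DataError,
    TreeIndex,
    average_mrca_state,
    build_rate_matrix,
    count_fusion_fission_events,
    fit_mk2_ard,
    log_likelihood,
    make_tip_vectors,
    marginal_ancestral_states,
    mk2_rate_matrix,
    mrca_state,
    stochastic_map,
)
from karyorates.ancestry import StochasticMapSummary
from .conftest import tree_from_newick


def brute_force_marginals(tree, tips, Q, states):
    idx = TreeIndex(tree)
    k = len(states)
    P = {
        i: expm(Q * idx.edge_length[i])
        for i in range(idx.n_nodes)
        if idx.parent[i] >= 0
    }
    internal = [i for i in range(idx.n_nodes) if i not in idx.tip_label]
    tipidx = {i: states.index(tips[idx.tip_label[i]]) for i in idx.tip_label}
    marg = {i: np.zeros(k) for i in internal}
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        amap.update(tipidx)
        p = 1.0 / k
        for i in range(idx.n_nodes):
            if idx.parent[i] >= 0:
                p *= P[i][amap[idx.parent[i]], amap[i]]
        for i in internal:
            marg[i][amap[i]] += p
    return {i: v / v.sum() for i, v in marg.items()}


class TestMarginalASR:
    def test_symmetric_two_tip_tree_gives_symmetric_root(self):
        tree = tree_from_newick("(A:0.5,B:0.5);")
        Q = build_rate_matrix(ChromosomeModel(n_min=4, n_max=5, rate_fission=0.7, rate_fusion=0.7))
        recon = marginal_ancestral_states(tree, {"A": 4, "B": 5}, Q)
        root = recon.probs[recon.index.root]
        assert root[0] == pytest.approx(root[1], abs=1e-12)

    def test_constant_tips_reconstruct_the_shared_state(self):
        tree = tree_from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        Q = build_rate_matrix(
            ChromosomeModel(n_min=3, n_max=9, rate_fission=0.5, rate_fusion=0.5, rate_polyploidy=0.1)
        )
        recon = marginal_ancestral_states(tree, {t: 6 for t in "ABCD"}, Q)
        for i in range(recon.index.n_nodes):
            assert recon.map_state[i] == 6

    def test_matches_brute_force_marginalization(self):
        tree = tree_from_newick("((A:0.4,B:0.6):0.5,C:0.9);")
        Q = build_rate_matrix(
            ChromosomeModel(n_min=3, n_max=6, rate_fission=0.7, rate_fusion=0.4, rate_polyploidy=0.3)
        )
        states = [3, 4, 5, 6]
        tips = {"A": 4, "B": 3, "C": 6}
        recon = marginal_ancestral_states(tree, tips, Q)
        expected = brute_force_marginals(tree, tips, Q.matrix, states)
        for i, v in expected.items():
            np.testing.assert_allclose(recon.probs[i], v, atol=1e-8)

    def test_certain_tips_keep_probability_one(self):
        tree = tree_from_newick("((A:0.4,B:0.6):0.5,C:0.9);")
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=5, rate_fission=1.0, rate_fusion=1.0))
        recon = marginal_ancestral_states(tree, {"A": 2, "B": 4, "C": 3}, Q)
        idx = recon.index
        for i, label in idx.tip_label.items():
            observed = {"A": 2, "B": 4, "C": 3}[label]
            assert recon.probs[i][recon.states.index(observed)] == pytest.approx(1.0)

    def test_node_probabilities_sum_to_one(self):
        tree = tree_from_newick("((A:0.4,B:0.6):0.5,C:0.9);")
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=8, rate_fission=0.9, rate_fusion=0.2))
        recon = marginal_ancestral_states(tree, {"A": 2, "B": 5, "C": 7}, Q)
        np.testing.assert_allclose(recon.probs.sum(axis=1), 1.0, atol=1e-9)


class TestMRCAState:
    def _recon(self):
        tree = tree_from_newick("((A:0.4,B:0.6):0.5,C:0.9);")
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=5, rate_fission=0.8, rate_fusion=0.6))
        return marginal_ancestral_states(tree, {"A": 2, "B": 4, "C": 3}, Q)

    def test_all_tips_give_root_vector(self):
        recon = self._recon()
        np.testing.assert_array_equal(
            mrca_state(recon, ["A", "B", "C"]), recon.probs[recon.index.root]
        )

    def test_single_tip_gives_degenerate_vector(self):
        recon = self._recon()
        v = mrca_state(recon, ["A"])
        assert v[recon.states.index(2)] == pytest.approx(1.0)

    def test_averaging_identical_trees_is_idempotent(self):
        recon = self._recon()
        np.testing.assert_allclose(
            average_mrca_state([recon, recon, recon], ["A", "B"]),
            mrca_state(recon, ["A", "B"]),
        )

    def test_missing_tip_rejected(self):
        with pytest.raises(DataError, match="Z"):
            mrca_state(self._recon(), ["A", "Z"])


class TestMk2ARD:
    def test_relabelling_swaps_rate_estimates(self):
        tree = tree_from_newick(
            "(((A:5,B:5):10,(C:5,D:5):10):20,((E:5,F:5):10,(G:5,H:5):10):20);"
        )
        scs = {"A": "XO", "B": "XO", "C": "XO", "D": "XY", "E": "XY", "F": "XY", "G": "XY", "H": "XO"}
        swapped = {t: ("XY" if s == "XO" else "XO") for t, s in scs.items()}
        (f1,), _ = fit_mk2_ard([tree], scs)
        (f2,), _ = fit_mk2_ard([tree], swapped)
        assert f1.q01 == pytest.approx(f2.q10, rel=1e-4, abs=1e-8)
        assert f1.q10 == pytest.approx(f2.q01, rel=1e-4, abs=1e-8)

    def test_identical_states_fit_is_boundary_flagged_at_zero(self):
        tree = tree_from_newick("(A:10,B:10);")
        with pytest.warns(UserWarning, match="unidentifiable"):
            (fit,), _ = fit_mk2_ard([tree], {"A": "XO", "B": "XO"})
        assert fit.boundary
        assert fit.q01 == pytest.approx(0.0, abs=1e-6)

    def test_mk2_likelihood_equals_two_state_chromosome_pruning(self):
        # the two-state chain is the chromosome CTMC restricted to {1, 2}
        tree = tree_from_newick("((A:0.4,B:0.6):0.5,C:0.9);")
        q01, q10 = 0.8, 0.3
        ll_mk2 = log_likelihood(
            tree,
            make_tip_vectors({"A": 0, "B": 1, "C": 0}, [0, 1]),
            mk2_rate_matrix(q01, q10),
        )
        chrom = build_rate_matrix(
            ChromosomeModel(n_min=1, n_max=2, rate_fission=q01, rate_fusion=q10)
        )
        ll_chrom = log_likelihood(
            tree, make_tip_vectors({"A": 1, "B": 2, "C": 1}, [1, 2]), chrom
        )
        assert ll_mk2 == pytest.approx(ll_chrom, abs=1e-10)

    def test_unknown_scs_tips_are_dropped(self):
        tree = tree_from_newick("((A:5,B:5):5,(C:5,D:5):5);")
        fits, _ = fit_mk2_ard([tree], {"A": "XO", "B": "XY", "C": "unknown", "D": "XO"})
        assert fits[0].n_tips == 3


class TestStochasticMap:
    def test_zero_rates_give_zero_transitions(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=4))
        summ = stochastic_map(tree, {t: 2 for t in "ABC"}, Q, n_maps=50, seed=1)
        assert summ.counts.empty or summ.counts.to_numpy().sum() == 0

    def test_fixed_seed_reproduces_counts(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        Q = mk2_rate_matrix(0.4, 0.4)
        tips = {"A": "XO", "B": "XY", "C": "XO"}
        s1 = stochastic_map(tree, tips, Q, n_maps=200, seed=7, states=["XO", "XY"])
        s2 = stochastic_map(tree, tips, Q, n_maps=200, seed=7, states=["XO", "XY"])
        assert s1.counts.equals(s2.counts)
        np.testing.assert_array_equal(s1.node_state_samples, s2.node_state_samples)

    def test_unconditioned_mean_counts_near_rate_times_length(self):
        tree = tree_from_newick("((A:10,B:10):5,(C:8,D:8):7);")
        q = 0.02
        total_length = 48.0
        summ = stochastic_map(
            tree,
            {t: None for t in "ABCD"},
            mk2_rate_matrix(q, q),
            n_maps=4000,
            seed=3,
            states=["XO", "XY"],
        )
        total = sum(summ.mean_counts.values())
        assert total == pytest.approx(q * total_length, rel=0.10)

    def test_mean_counts_match_per_map_average(self):
        tree = tree_from_newick("((A:10,B:10):5,(C:8,D:8):7);")
        summ = stochastic_map(
            tree,
            {"A": "XO", "B": "XY", "C": "XY", "D": "XO"},
            mk2_rate_matrix(0.05, 0.05),
            n_maps=300,
            seed=5,
            states=["XO", "XY"],
        )
        for key, mean in summ.mean_counts.items():
            assert mean == pytest.approx(summ.counts[key].mean())
            assert (summ.counts[key] >= 0).all()
            assert (summ.counts[key] == summ.counts[key].round()).all()


class TestEventCountComparison:
    def _summary(self, fusion, fission):
        import pandas as pd

        counts = pd.DataFrame({"fusion": [fusion], "fission": [fission]})
        return StochasticMapSummary(
            n_maps=1,
            counts=counts,
            mean_counts={"fusion": float(fusion), "fission": float(fission)},
            states=[1, 2],
            node_state_samples=np.zeros((1, 1), dtype=int),
        )

    def test_identical_counts_give_t_zero_p_one(self):
        maps = [self._summary(5, 5), self._summary(7, 7), self._summary(3, 3)]
        res = count_fusion_fission_events(maps)
        assert res.t_statistic == 0.0 and res.pvalue == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        maps = [self._summary(15, 5), self._summary(17, 7), self._summary(13, 3)]
        res = count_fusion_fission_events(maps)
        assert res.degenerate

    def test_paired_t_matches_textbook_computation(self):
        maps = [self._summary(5, 4), self._summary(7, 5), self._summary(9, 8)]
        res = count_fusion_fission_events(maps)
        d = np.array([1.0, 2.0, 1.0])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df=len(d) - 1)
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.pvalue == pytest.approx(p_hand, abs=1e-12)
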