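"""Rate-matrix construction, branch propagators, pruning likelihood."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from karyorates import (
    ChromosomeModel,
    DataError,
    Propagator,
    TraitLinkedRates,
    TreeIndex,
    back_transform_rates,
    build_rate_matrix,
    default_state_space,
    log_likelihood,
    make_tip_vectors,
    rescale_to_unit,
    tip_state_vector,
    transition_probabilities,
)
from .conftest import tree_from_newick


def brute_force_loglik(tree, tips, Q, states):
    """Sum over all internal-node state assignments (uniform root prior)."""
    idx = TreeIndex(tree)
    k = len(states)
    P = {
        i: expm(Q.matrix * idx.edge_length[i])
        for i in range(idx.n_nodes)
        if idx.parent[i] >= 0
    }
    internal = [i for i in range(idx.n_nodes) if i not in idx.tip_label]
    tipidx = {i: states.index(tips[idx.tip_label[i]]) for i in idx.tip_label}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        amap.update(tipidx)
        p = 1.0 / k
        for i in range(idx.n_nodes):
            if idx.parent[i] >= 0:
                p *= P[i][amap[idx.parent[i]], amap[i]]
        total += p
    return np.log(total)


class TestBuildRateMatrix:
    def test_all_rates_zero_gives_zero_matrix(self):
        Q = build_rate_matrix(ChromosomeModel(n_min=2, n_max=5))
        assert np.all(Q.matrix == 0)

    def test_fission_only_with_boundary_truncation(self):
        Q = build_rate_matrix(ChromosomeModel(n_min=2, n_max=4, rate_fission=1.0))
        expected = np.array([[-1.0, 1.0, 0.0], [0.0, -1.0, 1.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(Q.matrix, expected)

    def test_polyploidy_entries_by_enumeration(self):
        model = ChromosomeModel(n_min=2, n_max=8, rate_polyploidy=0.1)
        Q = build_rate_matrix(model)
        idx = Q.state_index()
        for n in range(2, 9):
            for m in range(2, 9):
                if m == 2 * n:
                    assert Q.matrix[idx[n], idx[m]] == pytest.approx(0.1)
                elif m != n:
                    assert Q.matrix[idx[n], idx[m]] == 0.0
        # 5 -> 10 would leave the space: no mass anywhere
        assert Q.matrix[idx[5]].sum() == pytest.approx(0.0)

    def test_demiploidy_targets_ceil_1p5n(self):
        Q = build_rate_matrix(ChromosomeModel(n_min=2, n_max=9, rate_demiploidy=0.2))
        idx = Q.state_index()
        assert Q.matrix[idx[4], idx[6]] == pytest.approx(0.2)
        assert Q.matrix[idx[5], idx[8]] == pytest.approx(0.2)  # ceil(7.5)

    def test_rows_sum_to_zero(self):
        Q = build_rate_matrix(
            ChromosomeModel(n_min=1, n_max=12, rate_fission=2.0, rate_fusion=3.0, rate_polyploidy=0.5)
        )
        np.testing.assert_allclose(Q.matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_unreachable_polyploidy_warns(self):
        with pytest.warns(UserWarning, match="polyploidy"):
            build_rate_matrix(ChromosomeModel(n_min=5, n_max=8, rate_polyploidy=0.1))

    def test_trait_linked_model_doubles_space_and_couples_states(self):
        tl = TraitLinkedRates(rates_state0=(1.0, 0.5, 0.0), rates_state1=(2.0, 0.2, 0.1), q01=0.3, q10=0.7)
        model = ChromosomeModel(n_min=2, n_max=5, trait_linked=tl)
        Q = build_rate_matrix(model)
        assert Q.size == 8 == model.n_states
        idx = Q.state_index()
        assert Q.matrix[idx[(3, 0)], idx[(4, 0)]] == pytest.approx(1.0)
        assert Q.matrix[idx[(3, 1)], idx[(4, 1)]] == pytest.approx(2.0)
        assert Q.matrix[idx[(3, 0)], idx[(3, 1)]] == pytest.approx(0.3)
        assert Q.matrix[idx[(3, 1)], idx[(3, 0)]] == pytest.approx(0.7)
        np.testing.assert_allclose(Q.matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_invalid_models_rejected(self):
        with pytest.raises(DataError):
            ChromosomeModel(n_min=0, n_max=5)
        with pytest.raises(DataError):
            ChromosomeModel(n_min=5, n_max=5)
        with pytest.raises(DataError):
            ChromosomeModel(n_min=1, n_max=5, rate_fission=-1)


class TestPropagator:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        fission=st.floats(0, 50),
        fusion=st.floats(0, 50),
        poly=st.floats(0, 2),
        t=st.floats(0, 2),
    )
    def test_rows_stochastic_for_any_rates_and_time(self, fission, fusion, poly, t):
        Q = build_rate_matrix(
            ChromosomeModel(n_min=1, n_max=15, rate_fission=fission, rate_fusion=fusion, rate_polyploidy=poly)
        )
        P = transition_probabilities(Q, t)
        assert P.min() >= 0
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_zero_length_branch_is_exact_identity(self):
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=6, rate_fission=3.0))
        np.testing.assert_array_equal(transition_probabilities(Q, 0.0), np.eye(6))

    def test_dyadic_fallback_matches_expm_in_asymmetric_regime(self):
        # strongly asymmetric rates: eigenbasis is ill-conditioned
        Q = build_rate_matrix(
            ChromosomeModel(n_min=1, n_max=80, rate_fission=105.0, rate_fusion=19.0, rate_polyploidy=1.7)
        )
        prop = Propagator(Q)
        assert not prop._use_eig
        v = np.zeros(80)
        v[10] = 1.0
        for t in (0.033, 0.41, 1.0):
            np.testing.assert_allclose(
                prop.apply(t, v), expm(Q.matrix * t) @ v, atol=1e-8
            )

    def test_batch_apply_matches_scalar_apply(self):
        Q = build_rate_matrix(
            ChromosomeModel(n_min=1, n_max=10, rate_fission=4.0, rate_fusion=3.0)
        )
        prop = Propagator(Q)
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(10, 4))
        ts = np.array([0.0, 0.2, 0.7, 1.4])
        batch = prop.apply_batch(ts, X)
        for b in range(4):
            np.testing.assert_allclose(batch[:, b], prop.apply(ts[b], X[:, b]), atol=1e-10)


class TestRescaling:
    def test_rescale_divides_by_root_depth(self):
        tree = tree_from_newick("((A:100,B:100):150,C:250);")
        unit, factor = rescale_to_unit(tree)
        assert factor == pytest.approx(250.0)
        assert unit.max_distance_from_root() == pytest.approx(1.0)

    def test_unit_tree_unchanged(self):
        tree = tree_from_newick("((A:0.4,B:0.4):0.6,C:1.0);")
        unit, factor = rescale_to_unit(tree)
        assert factor == pytest.approx(1.0)

    def test_rescale_then_back_multiply_recovers_lengths(self):
        tree = tree_from_newick("((A:123.4,B:123.4):76.6,C:200.0);")
        unit, factor = rescale_to_unit(tree)
        original = sorted(
            e.length for e in tree.preorder_edge_iter() if e.length is not None
        )
        recovered = sorted(
            e.length * factor for e in unit.preorder_edge_iter() if e.length is not None
        )
        np.testing.assert_allclose(recovered, original, atol=1e-12)

    def test_back_transform_arithmetic_and_inverse(self):
        assert back_transform_rates(0.5, 250.0) == pytest.approx(0.002)
        assert back_transform_rates(1.7, 1.0) == pytest.approx(1.7)
        assert back_transform_rates(back_transform_rates(3.3, 0.25), 1 / 0.25) == pytest.approx(3.3)


class TestTipVectors:
    def test_singleton_candidate_and_missing(self):
        states = [2, 3, 4]
        np.testing.assert_array_equal(tip_state_vector(3, states), [0, 1, 0])
        np.testing.assert_array_equal(tip_state_vector({2, 4}, states), [0.5, 0, 0.5])
        np.testing.assert_array_equal(tip_state_vector(None, states), [1, 1, 1])

    def test_candidates_outside_space_rejected(self):
        with pytest.raises(DataError):
            tip_state_vector({9}, [2, 3, 4])

    def test_default_state_space_bound(self):
        assert default_state_space([5, {11, 12}, 7]) == (1, 25)


class TestLogLikelihood:
    def test_zero_branches_same_state_gives_log_one_over_k(self):
        tree = tree_from_newick("(A:0.0,B:0.0);")
        states = list(range(1, 7))
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=6, rate_fission=2.0, rate_fusion=1.0))
        tips = make_tip_vectors({"A": 3, "B": 3}, states)
        assert log_likelihood(tree, tips, Q) == pytest.approx(np.log(1 / 6))

    def test_two_tip_closed_form_oracle(self):
        t = 0.8
        tree = tree_from_newick(f"(A:{t},B:{t});")
        states = list(range(2, 7))
        Q = build_rate_matrix(
            ChromosomeModel(n_min=2, n_max=6, rate_fission=0.9, rate_fusion=0.4, rate_polyploidy=0.2)
        )
        P = expm(Q.matrix * t)
        a, b = states.index(3), states.index(5)
        expected = np.log(sum(P[r, a] * P[r, b] / len(states) for r in range(len(states))))
        tips = make_tip_vectors({"A": 3, "B": 5}, states)
        assert log_likelihood(tree, tips, Q) == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_child_exchange(self):
        states = list(range(1, 9))
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=8, rate_fission=1.2, rate_fusion=0.7))
        tips = make_tip_vectors({"A": 2, "B": 5, "C": 7}, states)
        t1 = tree_from_newick("((A:0.2,B:0.5):0.3,C:0.8);")
        t2 = tree_from_newick("((B:0.5,A:0.2):0.3,C:0.8);")
        assert log_likelihood(t1, tips, Q) == pytest.approx(log_likelihood(t2, tips, Q), abs=1e-12)

    def test_matches_brute_force_enumeration(self, four_tip_tree):
        states = list(range(2, 7))
        Q = build_rate_matrix(
            ChromosomeModel(n_min=2, n_max=6, rate_fission=0.8, rate_fusion=0.5, rate_polyploidy=0.2)
        )
        tips = {"A": 3, "B": 2, "C": 5, "D": 4}
        ll = log_likelihood(four_tip_tree, make_tip_vectors(tips, states), Q)
        assert ll == pytest.approx(brute_force_loglik(four_tip_tree, tips, Q, states), abs=1e-8)

    def test_rate_time_rescaling_leaves_likelihood_unchanged(self):
        c = 3.7
        states = list(range(1, 11))
        tips = make_tip_vectors({"A": 2, "B": 6, "C": 9, "D": 4}, states)
        m1 = ChromosomeModel(n_min=1, n_max=10, rate_fission=1.1, rate_fusion=0.6, rate_polyploidy=0.3)
        m2 = ChromosomeModel(
            n_min=1, n_max=10, rate_fission=1.1 * c, rate_fusion=0.6 * c, rate_polyploidy=0.3 * c
        )
        t1 = tree_from_newick("((A:0.3,B:0.7):0.4,(C:0.5,D:0.2):0.6);")
        t2 = tree_from_newick(
            f"((A:{0.3/c},B:{0.7/c}):{0.4/c},(C:{0.5/c},D:{0.2/c}):{0.6/c});"
        )
        ll1 = log_likelihood(t1, tips, build_rate_matrix(m1))
        ll2 = log_likelihood(t2, tips, build_rate_matrix(m2))
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_complex_model_with_zero_polyploidy_equals_simple(self, four_tip_tree):
        states = list(range(1, 9))
        tips = make_tip_vectors({"A": 2, "B": 4, "C": 7, "D": 5}, states)
        simple = ChromosomeModel(n_min=1, n_max=8, rate_fission=1.5, rate_fusion=0.8)
        complex_ = ChromosomeModel(
            n_min=1, n_max=8, rate_fission=1.5, rate_fusion=0.8, rate_polyploidy=0.0
        )
        assert log_likelihood(four_tip_tree, tips, build_rate_matrix(simple)) == log_likelihood(
            four_tip_tree, tips, build_rate_matrix(complex_)
        )

    def test_all_zero_tip_vector_names_the_tip(self, three_tip_tree):
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=4, rate_fission=1.0))
        tips = {"A": np.array([1.0, 0, 0, 0]), "B": np.zeros(4), "C": np.array([0, 1.0, 0, 0])}
        with pytest.raises(DataError, match="B"):
            log_likelihood(three_tip_tree, tips, Q)

    def test_observed_root_prior(self):
        tree = tree_from_newick("(A:0.0,B:0.0);")
        states = [1, 2]
        Q = build_rate_matrix(ChromosomeModel(n_min=1, n_max=2))
        tips = make_tip_vectors({"A": 1, "B": 1}, states)
        assert log_likelihood(tree, tips, Q, root_prior="observed") == pytest.approx(0.0)
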