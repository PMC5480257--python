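import numpy as np
import pytest
from scipy.linalg import expm

from biogeodiv.dec import (AreaSystem, DECModel, DECParams, build_q_matrix,
                           enumerate_states, fit_ml, range_label,
                           split_scenarios, tree_log_likelihood)
from biogeodiv.synthdata import SimConfig, simulate_ranges, simulate_trees
from biogeodiv.treeio import TimeTree

A = frozenset("A")
B = frozenset("B")
AB = frozenset("AB")


class TestStateSpace:
    def test_max_size_one_excludes_pairs(self):
        sys_ = AreaSystem.from_pairs("AB", [("A", "B")], 1)
        assert enumerate_states(sys_) == [frozenset(), A, B]

    def test_connectivity_rule(self):
        sys_ = AreaSystem.from_pairs("ABC", [("A", "B"), ("B", "C")], 2)
        labels = [range_label(s, sys_) for s in enumerate_states(sys_)]
        assert labels == ["-", "A", "B", "C", "AB", "BC"]

    def test_complete_eight_areas_count(self):
        sys_ = AreaSystem.complete("ABCDEFGH", 2)
        assert len(enumerate_states(sys_)) == 1 + 8 + 28

    def test_scenarios_singleton_and_pair(self):
        allowed = set(enumerate_states(AreaSystem.from_pairs(
            "AB", [("A", "B")], 2)))
        assert split_scenarios(A, allowed) == [(A, A)]
        pair = split_scenarios(AB, allowed)
        assert len(pair) == 6
        assert (A, B) in pair and (B, A) in pair
        assert (A, AB) in pair and (AB, B) in pair


class TestQMatrix:
    def test_no_expansion_when_max_size_one(self):
        sys_ = AreaSystem.from_pairs("AB", [("A", "B")], 1)
        q = build_q_matrix(sys_, DECParams(0.1, 0.05))
        states = enumerate_states(sys_)
        i = states.index(A)
        row = {range_label(states[j], sys_): q[i, j]
               for j in range(len(states)) if q[i, j] > 0}
        assert row == {"-": pytest.approx(0.05)}

    def test_hand_enumerated_two_area_rates(self, ab_system):
        states = enumerate_states(ab_system)
        q = build_q_matrix(ab_system, DECParams(0.1, 0.05), states)
        idx = {s: i for i, s in enumerate(states)}
        assert q[idx[A], idx[AB]] == pytest.approx(0.1)
        assert q[idx[A], idx[frozenset()]] == pytest.approx(0.05)
        assert q[idx[AB], idx[A]] == pytest.approx(0.05)
        assert q[idx[AB], idx[B]] == pytest.approx(0.05)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(q[idx[frozenset()]] == 0.0)   # absorbing

    def test_zero_rates_zero_matrix(self, chain5_system):
        q = build_q_matrix(chain5_system, DECParams(0.0, 0.0))
        assert np.all(q == 0.0)

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_propagator_rows_sum_to_one(self, chain5_system, t):
        q = build_q_matrix(chain5_system, DECParams(0.3, 0.1))
        p = expm(q * t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestLikelihood:
    def test_degenerate_dynamics(self, cherry, ab_system):
        # d = e = 0: transitions are identity, only A|A contributes, so
        # logL is the log-weight of root state A among the three
        # non-empty states
        ll = tree_log_likelihood(cherry, {"A": A, "B": A}, ab_system,
                                 DECParams(0.0, 0.0))
        assert ll == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)

    def test_matches_discretized_oracle(self, cherry, ab_system,
                                        dec_oracle):
        params = DECParams(0.1, 0.05)
        ll = tree_log_likelihood(cherry, {"A": A, "B": B}, ab_system,
                                 params)
        ll_oracle, _ = dec_oracle(ab_system, (A, B), (1.0, 1.0), params)
        assert abs(ll - ll_oracle) / abs(ll_oracle) < 1e-6

    def test_child_swap_symmetry(self, ab_system):
        params = DECParams(0.13, 0.04)
        t1 = TimeTree.from_newick("((A:1,B:1):0.5,C:1.5);")
        t2 = TimeTree.from_newick("(C:1.5,(B:1,A:1):0.5);")
        ranges = {"A": A, "B": B, "C": A}
        assert tree_log_likelihood(t1, ranges, ab_system, params) == \
            pytest.approx(tree_log_likelihood(t2, ranges, ab_system,
                                              params), abs=1e-12)

    def test_single_area_pure_survival(self):
        # one area, e = 0: the range cannot change and the only root
        # state is certain, so logL = 0
        sys_ = AreaSystem.from_pairs("A", [], 1)
        t = TimeTree.from_newick("((x:1,y:1):1,z:2);")
        ranges = {k: A for k in "xyz"}
        assert tree_log_likelihood(t, ranges, sys_, DECParams(0.2, 0.0)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_disallowed_tip_range_names_tip(self, cherry):
        sys_ = AreaSystem.from_pairs("ABC", [("A", "B")], 2)
        with pytest.raises(ValueError, match="'B'"):
            DECModel(cherry, {"A": A, "B": frozenset("AC")}, sys_)

    def test_perturbed_tip_lowers_mean_likelihood(self, chain5_system):
        # on average over simulations, moving one tip's observed range
        # further from its simulated truth lowers the likelihood
        params = DECParams(0.2, 0.05)
        area_order = "ABCDE"
        deltas = {1: [], 2: []}
        n_used = 0
        for rep in range(300):
            cfg = SimConfig(seed=1000 + rep, n_tips=8, crown_age=10.0,
                            rates=(0.3,), shift_ages=(),
                            n_posterior_trees=0)
            tree, _ = simulate_trees(cfg)
            ranges = simulate_ranges(tree, chain5_system, params,
                                     frozenset("C"), seed=rep)
            singles = [t for t, r in ranges.items()
                       if len(r) == 1 and max(r) <= "C"]
            if not singles:
                continue
            tip = singles[0]
            true_area = next(iter(ranges[tip]))
            base = tree_log_likelihood(tree, ranges, chain5_system, params)
            for dist in (1, 2):
                moved = area_order[area_order.index(true_area) + dist]
                perturbed = dict(ranges)
                perturbed[tip] = frozenset(moved)
                deltas[dist].append(
                    tree_log_likelihood(tree, perturbed, chain5_system,
                                        params) - base)
            n_used += 1
        assert n_used >= 100
        assert np.mean(deltas[1]) < 0.0
        assert np.mean(deltas[2]) < np.mean(deltas[1])


class TestSplitProbs:
    def test_fixed_ranges_single_scenario(self, ab_system):
        t = TimeTree.from_newick("((x:1,y:1):1,z:2);")
        model = DECModel(t, {"x": A, "y": A, "z": A}, ab_system)
        node = next(nd for nd in t.tree.preorder_internal_node_iter()
                    if nd.parent_node is not None)
        scns = model.node_split_probs(DECParams(0.0, 0.0), node)
        assert len(scns) == 1
        assert scns[0].left_range == A and scns[0].right_range == A
        assert scns[0].rel_prob == pytest.approx(1.0)
        assert scns[0].ancestor_range == A

    def test_matches_exhaustive_clamping_oracle(self, cherry, ab_system,
                                                dec_oracle):
        params = DECParams(0.1, 0.05)
        model = DECModel(cherry, {"A": A, "B": B}, ab_system)
        got = model.node_split_probs(params, cherry.tree.seed_node)
        _, oracle = dec_oracle(ab_system, (A, B), (1.0, 1.0), params)
        assert sum(s.rel_prob for s in got) == pytest.approx(1.0,
                                                             abs=1e-9)
        for s in got:
            key = (s.left_range, s.right_range)
            assert s.rel_prob == pytest.approx(oracle[key], rel=1e-6,
                                               abs=1e-9)

    def test_normalization_on_random_instance(self, chain5_system):
        cfg = SimConfig(seed=77, n_tips=12, crown_age=12.0, rates=(0.3,),
                        shift_ages=(), n_posterior_trees=0)
        tree, _ = simulate_trees(cfg)
        ranges = simulate_ranges(tree, chain5_system, DECParams(0.2, 0.02),
                                 frozenset("C"), seed=4)
        model = DECModel(tree, ranges, chain5_system)
        params = DECParams(0.15, 0.03)
        for node in tree.tree.preorder_internal_node_iter():
            scns = model.node_split_probs(params, node)
            assert sum(s.rel_prob for s in scns) == pytest.approx(
                1.0, abs=1e-9)

    def test_tip_node_rejected(self, cherry, ab_system):
        model = DECModel(cherry, {"A": A, "B": B}, ab_system)
        leaf = next(cherry.tree.leaf_node_iter())
        with pytest.raises(ValueError, match="internal"):
            model.node_split_probs(DECParams(0.1, 0.1), leaf)


class TestFit:
    def test_no_dispersal_signal_hits_lower_bound(self, ab_system):
        t = TimeTree.from_newick("((x:1,y:1):1,(z:1,w:1):1);")
        res = fit_ml(t, {k: A for k in "xyzw"}, ab_system, seed=0)
        assert res.params.d <= 1e-4      # effectively zero dispersal

    def test_restarts_agree(self, chain5_system):
        cfg = SimConfig(seed=8, n_tips=15, crown_age=14.0, rates=(0.25,),
                        shift_ages=(), n_posterior_trees=0)
        tree, _ = simulate_trees(cfg)
        ranges = simulate_ranges(tree, chain5_system, DECParams(0.2, 0.05),
                                 frozenset("C"), seed=8)
        model = DECModel(tree, ranges, chain5_system)
        lls = [model.fit(n_restarts=1, seed=s).llf for s in (1, 2, 3)]
        assert max(lls) - min(lls) < 1e-4

    def test_summary_mentions_rates(self, cherry, ab_system):
        res = fit_ml(cherry, {"A": A, "B": B}, ab_system, seed=0)
        text = res.summary()
        assert "dispersal" in text and "logL" in text
        assert res.converged
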