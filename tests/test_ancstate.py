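"""Mk likelihood, marginal reconstruction, stochastic mapping."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from macrodiv.ancstate import (MkModel, mk_loglik, MkAncestralModel,
                               ml_marginal_reconstruction, stochastic_map)
from macrodiv.simulate import simulate_yule, simulate_mk_characters
from macrodiv.tree import read_newick


def brute_force_loglik(tree, annot, Q, pi):
    """Sum the joint likelihood over every interior-state assignment."""
    dt = tree.dendropy_tree
    internal = [nd for nd in dt.preorder_node_iter() if nd.child_nodes()]
    K = Q.shape[0]
    P = {nd: expm(Q * nd.edge.length) for nd in dt.preorder_node_iter()
         if nd.parent_node is not None}
    total = 0.0
    for assign in itertools.product(range(K), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        like = pi[amap[dt.seed_node]]
        for nd in dt.preorder_node_iter():
            if nd.parent_node is None:
                continue
            s = (amap[nd] if nd.child_nodes()
                 else int(annot[nd.taxon.label]))
            like *= P[nd][amap[nd.parent_node], s]
        total += like
    return math.log(total)


class TestMkLoglik:
    def test_two_tip_closed_form(self):
        t = read_newick("(A:3,B:3);")
        r = 0.07
        p_same = 0.5 * (1 + math.exp(-2 * r * 3))
        L = 0.5 * (p_same ** 2 + (1 - p_same) ** 2)
        assert mk_loglik(t, {"A": 0, "B": 0}, MkModel(K=2, rate=r)) == \
            pytest.approx(math.log(L), abs=1e-12)

    def test_zero_rate_limit(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        ll = mk_loglik(t, {"A": 1, "B": 1, "C": 1},
                       MkModel(K=4, rate=1e-9))
        assert ll == pytest.approx(math.log(0.25), abs=1e-4)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for trial in range(12):
            n = int(rng.integers(3, 7))
            K = int(rng.integers(2, 4))
            tree = simulate_yule(n, 1.0, seed=trial)
            r = float(rng.uniform(0.05, 1.0))
            model = MkModel(K=K, rate=r)
            Q = model.generator()
            annot = simulate_mk_characters(tree, Q, seed=trial + 100)
            annot = {k: v % K for k, v in annot.items()}
            got = mk_loglik(tree, annot, model)
            want = brute_force_loglik(tree, annot, Q, model.root_prior)
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_annotation_rejected(self):
        t = read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            mk_loglik(t, {"A": 0}, MkModel(K=2))

    def test_invalid_generator_rejected(self):
        with pytest.raises(ValueError):
            MkModel(K=2, Q=np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestMarginals:
    def test_constant_character_reconstructed_everywhere(self):
        tree = simulate_yule(12, 0.5, seed=4)
        annot = {l: 2 for l in tree.tip_labels}
        rec = MkAncestralModel(tree, annot, K=4).fit()
        for p in rec.node_probs.values():
            assert np.argmax(p) == 2
            assert p[2] > 0.99

    def test_matches_brute_force_posterior(self):
        tree = read_newick("((A:1,B:1):1.5,(C:2,D:2):0.5);")
        annot = {"A": 0, "B": 2, "C": 1, "D": 0}
        K, r = 3, 0.3
        model = MkModel(K=K, rate=r)
        Q = model.generator()
        P = {bl: expm(Q * bl) for bl in (1.0, 1.5, 2.0, 0.5)}
        brute = np.zeros(K)
        for root, n1, n2 in itertools.product(range(K), repeat=3):
            brute[n1] += ((1 / K) * P[1.5][root, n1] * P[0.5][root, n2]
                          * P[1.0][n1, annot["A"]] * P[1.0][n1, annot["B"]]
                          * P[2.0][n2, annot["C"]] * P[2.0][n2, annot["D"]])
        brute /= brute.sum()
        rec = MkAncestralModel(tree, annot, K=K).fit(rate=r)
        np.testing.assert_allclose(rec.node_probs[frozenset("AB")], brute,
                                   atol=1e-10)

    def test_state_relabelling_symmetry(self):
        tree = simulate_yule(10, 0.5, seed=5)
        annot = simulate_mk_characters(tree, MkModel(K=3, rate=0.2
                                                     ).generator(), seed=5)
        perm = {0: 2, 1: 0, 2: 1}
        annot2 = {k: perm[v] for k, v in annot.items()}
        r = 0.15
        rec1 = MkAncestralModel(tree, annot, K=3).fit(rate=r)
        rec2 = MkAncestralModel(tree, annot2, K=3).fit(rate=r)
        for clade, p in rec1.node_probs.items():
            q = rec2.node_probs[clade]
            for old, new in perm.items():
                assert p[old] == pytest.approx(q[new], abs=1e-10)

    def test_root_recovery_with_strong_signal(self):
        # low-rate 4-state characters: the true root state should win
        hits = 0
        B = 80
        for s in range(B):
            tree = simulate_yule(50, 1.0, seed=2000 + s)
            rate = 0.05 / tree.crown_age
            Q = MkModel(K=4, rate=rate).generator()
            rng = np.random.default_rng(s)
            root_state = int(rng.integers(4))
            pi = np.zeros(4)
            pi[root_state] = 1.0
            annot = simulate_mk_characters(tree, Q, root_distribution=pi,
                                           seed=s + 1)
            rec = MkAncestralModel(tree, annot, K=4).fit()
            root_clade = frozenset(tree.tip_labels)
            hits += int(np.argmax(rec.node_probs[root_clade])) == root_state
        assert hits / B >= 0.9


class TestStochasticMap:
    def test_fixed_rate_matches_marginals(self):
        tree = simulate_yule(10, 0.5, seed=6)
        Q = MkModel(K=3, rate=0.3).generator()
        annot = simulate_mk_characters(tree, Q, seed=6)
        r = 0.25
        rec = ml_marginal_reconstruction(tree, annot, K=3, rate=r)
        summ = stochastic_map(tree, annot, K=3,
                              rate_prior=("fixed", r), n_draws=2000,
                              seed=7)
        for clade, p in rec.node_probs.items():
            mpp = summ.mpp[clade]
            se = np.sqrt(np.maximum(p * (1 - p), 1e-4) / 2000)
            assert np.all(np.abs(mpp - p) < 4 * se + 1e-3)

    def test_constant_character_certain(self):
        tree = simulate_yule(8, 0.5, seed=8)
        annot = {l: 1 for l in tree.tip_labels}
        summ = stochastic_map(tree, annot, K=3,
                              rate_prior=("gamma", 2.0,
                                          0.005 / tree.crown_age),
                              n_draws=300, seed=9)
        for clade, p in summ.mpp.items():
            assert p[1] > 0.95

    def test_duplicate_trees_aggregate_like_double_draws(self):
        tree = simulate_yule(9, 0.5, seed=10)
        Q = MkModel(K=2, rate=0.3).generator()
        annot = simulate_mk_characters(tree, Q, seed=10)
        one = stochastic_map([tree, tree], annot, K=2,
                             rate_prior=("fixed", 0.2), n_draws=400,
                             seed=11)
        assert all(v == 2 for v in one.tree_count.values())
        two = stochastic_map(tree, annot, K=2, rate_prior=("fixed", 0.2),
                             n_draws=800, seed=11)
        for clade in one.mpp:
            assert np.all(np.abs(one.mpp[clade] - two.mpp[clade]) < 0.08)

    def test_node_matching_across_different_topologies(self):
        t1 = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        t2 = read_newick("(((A:1,B:1):0.5,C:1.5):0.5,D:2);")
        annot = {"A": 0, "B": 0, "C": 1, "D": 1}
        summ = stochastic_map([t1, t2], annot, K=2,
                              rate_prior=("fixed", 0.3), n_draws=50,
                              seed=12)
        assert summ.tree_count[frozenset("AB")] == 2      # in both trees
        assert summ.tree_count[frozenset("CD")] == 1      # only in t1
        assert summ.tree_count[frozenset("ABCD")] == 2    # the root
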