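"""Simulator behaviour: determinism, distributional laws, reductions."""

import math

import numpy as np
import pytest
from scipy.stats import kstest, chisquare

from macrodiv import _core
from macrodiv.gamma import gamma_of_tree
from macrodiv.simulate import (SubsamplingScheme, simulate_yule, simulate_bd,
                               simulate_multirate_yule, simulate_bisse,
                               simulate_mk_characters, subsample)


def _null_gammas(n, B, rng, m=None, alpha=0.0):
    out = np.empty(B)
    for b in range(B):
        parent, age, tips, _ = _core.yule_arrays(n, rng)
        if m is not None:
            keep = _core.choose_tips(parent, age, tips, m, rng, alpha=alpha)
            bt = _core.pruned_branching_times(parent, age, keep)
        else:
            bt = np.sort(np.asarray([a for a in age if a > 0]))[::-1]
        out[b] = _core.gamma_from_branching_times(bt)
    return out


class TestYule:
    def test_deterministic_under_seed(self):
        a = simulate_yule(20, 1.0, seed=5).to_newick()
        b = simulate_yule(20, 1.0, seed=5).to_newick()
        c = simulate_yule(20, 1.0, seed=6).to_newick()
        assert a == b
        assert a != c

    def test_rate_is_pure_time_scale(self):
        t1 = simulate_yule(15, 1.0, seed=9)
        t2 = simulate_yule(15, 4.0, seed=9)
        np.testing.assert_allclose(t2.branching_times(),
                                   t1.branching_times() / 4.0, rtol=1e-12)

    def test_gamma_null_standard_normal(self):
        rng = np.random.default_rng(21)
        g = _null_gammas(50, 2000, rng)
        se = g.std() / math.sqrt(len(g))
        assert abs(g.mean()) < 3 * se
        assert abs(g.std() - 1.0) < 0.1

    def test_interval_durations_exponential_means(self):
        # E[g_k] = 1/(k lam)
        rng = np.random.default_rng(33)
        lam, n, B = 2.0, 10, 3000
        gs = np.empty((B, n - 1))
        for b in range(B):
            parent, age, tips, _ = _core.yule_arrays(n, rng, rates=[lam])
            bt = np.sort(np.asarray([a for a in age if a > 0]))[::-1]
            gs[b] = np.concatenate([-np.diff(bt), bt[-1:]])
        k = np.arange(2, n + 1)
        expect = 1.0 / (k * lam)
        se = gs.std(axis=0) / math.sqrt(B)
        assert np.all(np.abs(gs.mean(axis=0) - expect) < 3 * se)


class TestBirthDeath:
    def test_reduces_to_yule_at_mu_zero(self):
        rng_ages = [simulate_bd(20, 1.0, 0.0, seed=s).crown_age
                    for s in range(300)]
        yule_ages = [simulate_yule(20, 1.0, seed=10_000 + s).crown_age
                     for s in range(300)]
        assert kstest(rng_ages, yule_ages).pvalue > 0.01

    def test_pull_of_the_present(self):
        # strong extinction biases reconstructed gammas positive
        g = [gamma_of_tree(simulate_bd(40, 1.0, 0.8, seed=s))
             for s in range(150)]
        g = np.array(g)
        assert g.mean() > 3 * g.std() / math.sqrt(len(g))

    def test_minimal_size(self):
        t = simulate_bd(3, 1.0, 0.3, seed=1)
        assert len(t.branching_times()) == 2

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_bd(10, 0.5, 0.5, seed=0)


class TestMultirate:
    def test_single_rate_equals_yule(self):
        a = simulate_yule(25, 0.7, seed=4).to_newick()
        b = simulate_multirate_yule(25, [0.7], [], seed=4).to_newick()
        assert a == b

    def test_equal_rates_match_pure_yule_gamma(self):
        g1 = [gamma_of_tree(simulate_multirate_yule(30, [1.0, 1.0], [0.5],
                                                    seed=s))
              for s in range(300)]
        g2 = [gamma_of_tree(simulate_yule(30, 1.0, seed=5000 + s))
              for s in range(300)]
        assert kstest(g1, g2).pvalue > 0.01

    def test_realized_shift_ages_recorded(self):
        t = simulate_multirate_yule(40, [3.0, 0.5], [0.6], seed=8)
        assert len(t.shift_ages) == 1
        assert t.shift_ages[0] == pytest.approx(t.crown_age - 0.6)

    def test_inconsistent_shifts_rejected(self):
        with pytest.raises(ValueError):
            simulate_multirate_yule(10, [1.0, 2.0, 3.0], [2.0, 1.0], seed=0)


class TestBisseSim:
    def test_no_flips_all_root_state(self):
        tree, states = simulate_bisse(20, (0.5, 0.5, 0.0, 0.0, 0.0, 0.0),
                                      root_state=0, seed=3)
        assert set(states.values()) == {0}

    def test_higher_lambda1_enriches_state1(self):
        fracs = []
        for s in range(120):
            _, states = simulate_bisse(
                40, (0.25, 0.5, 0.0, 0.0, 0.05, 0.05), seed=s)
            v = list(states.values())
            fracs.append(np.mean(v))
        assert np.mean(fracs) > 0.5

    def test_state_independent_tree_matches_bd(self):
        ages1 = [simulate_bisse(25, (0.6, 0.6, 0.2, 0.2, 0.1, 0.1),
                                seed=s)[0].crown_age for s in range(200)]
        ages2 = [simulate_bd(25, 0.6, 0.2, seed=7000 + s).crown_age
                 for s in range(200)]
        assert kstest(ages1, ages2).pvalue > 0.01


class TestSubsample:
    def test_identity_at_full_size(self):
        t = simulate_yule(15, 1.0, seed=2)
        s = subsample(t, SubsamplingScheme(mode="random", m=15), seed=0)
        np.testing.assert_allclose(s.branching_times(), t.branching_times())

    def test_incomplete_sampling_biases_gamma_negative(self):
        # the artefact the MCCR test corrects: complete trees of 300 taxa
        # sampled down to 40 look strongly decelerating
        rng = np.random.default_rng(17)
        g = _null_gammas(300, 200, rng, m=40)
        assert g.mean() < -2.0

    def test_heavy_subsampling_very_negative(self):
        rng = np.random.default_rng(18)
        g = _null_gammas(1506, 60, rng, m=218 // 4)
        assert g.mean() < -5.0

    def test_diversified_sampling_deepens_gamma(self):
        rng = np.random.default_rng(19)
        g0 = _null_gammas(120, 150, rng, m=30, alpha=0.0)
        g1 = _null_gammas(120, 150, rng, m=30, alpha=1.0)
        assert g1.mean() < g0.mean()

    def test_oversampling_rejected(self):
        t = simulate_yule(10, 1.0, seed=1)
        with pytest.raises(ValueError):
            subsample(t, SubsamplingScheme(mode="random", m=11), seed=0)


class TestMkCharacters:
    def test_zero_rate_preserves_root_state(self):
        t = simulate_yule(20, 1.0, seed=6)
        Q = np.zeros((3, 3))
        states = simulate_mk_characters(t, Q, root_distribution=[0, 1, 0],
                                        seed=0)
        assert set(states.values()) == {1}

    def test_two_state_transition_probability(self):
        # per-branch flip probability p = (1 - e^{-2rt})/2 on a 2-tip tree
        from macrodiv.tree import read_newick
        t = read_newick("(A:2,B:2);")
        r = 0.25
        Q = [[-r, r], [r, -r]]
        rng_seed_hits = 0
        B = 2000
        for s in range(B):
            st = simulate_mk_characters(t, Q, seed=s)
            rng_seed_hits += st["A"] != st["B"]
        p = 0.5 * (1 - math.exp(-2 * r * 2))
        expect = 2 * p * (1 - p)       # differ iff exactly one branch flips
        se = math.sqrt(expect * (1 - expect) / B)
        assert abs(rng_seed_hits / B - expect) < 3 * se

    def test_high_rate_reaches_stationarity(self):
        t = simulate_yule(60, 0.3, seed=12)
        K = 3
        r = 50.0 / t.crown_age
        Q = np.full((K, K), r)
        np.fill_diagonal(Q, -(K - 1) * r)
        counts = np.zeros(K)
        for s in range(30):
            st = simulate_mk_characters(t, Q, seed=s)
            for v in st.values():
                counts[v] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_invalid_q_rejected(self):
        t = simulate_yule(5, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_mk_characters(t, [[0.0, 1.0], [1.0, 0.0]], seed=0)
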