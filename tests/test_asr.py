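"""Ancestral-state inference: parsimony, ML pruning/marginals, MCMC."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from paleoasr import (
    AsrError,
    McmcSettings,
    MkModel,
    bayes_asr,
    fit_mk,
    marginal_asr_ml,
    mk_loglik,
    parse_newick,
    rate_confidence_interval,
    sankoff_parsimony,
    unit_branch_lengths,
)
from paleoasr.coding import ALL_STATES, CharacterCoding

from conftest import (
    enumerate_loglik,
    enumerate_marginals,
    enumerate_sankoff,
    random_coding,
    random_tree,
)


def coding_of(**states):
    return CharacterCoding(
        {k: (ALL_STATES if v == "?" else frozenset(v if isinstance(v, (set, frozenset)) else {v}))
         for k, v in states.items()}
    )


class TestMkModel:
    def test_er_closed_form_matches_matrix_exponential(self):
        q, t = 0.07, 3.5
        model = MkModel(3, "ER", np.array([q]))
        P = model.transition_matrix(t)
        assert np.allclose(P, expm(model.q_matrix() * t), atol=1e-12)
        e = math.exp(-3 * q * t)
        assert P[0, 0] == pytest.approx(1 / 3 + 2 / 3 * e)
        assert P[0, 1] == pytest.approx(1 / 3 - 1 / 3 * e)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_rate_count_validation(self):
        with pytest.raises(AsrError):
            MkModel(3, "SYM", np.array([0.1]))
        with pytest.raises(AsrError):
            MkModel(3, "ER", np.array([-0.1]))

    def test_stationary_prior_uniform_for_er(self):
        model = MkModel(3, "ER", np.array([0.2]), root_prior="stationary")
        assert np.allclose(model.prior_vector(), 1 / 3)

    def test_sym_and_ard_rows_sum_to_zero(self):
        for par, n in (("SYM", 3), ("ARD", 6)):
            Q = MkModel(3, par, np.linspace(0.1, 0.6, n)).q_matrix()
            assert np.allclose(Q.sum(axis=1), 0.0)


class TestSankoff:
    def test_hand_worked_three_tip_example(self):
        t = parse_newick("((A,B),C);")
        res = sankoff_parsimony(t, coding_of(A=1, B=1, C=0))
        assert res.cost == 1
        assert res.node_states[t.root.id] == {0, 1}
        assert res.node_states[t.mrca({"A", "B"}).id] == {1}

    def test_constant_character_zero_cost(self):
        t = parse_newick("((A,B),(C,D));")
        res = sankoff_parsimony(t, coding_of(A=2, B=2, C=2, D=2))
        assert res.cost == 0
        assert all(s == {2} for s in res.node_states.values())

    def test_all_uncertain_zero_cost_full_sets(self):
        t = parse_newick("((A,B),C);")
        res = sankoff_parsimony(t, coding_of(A="?", B="?", C="?"))
        assert res.cost == 0
        assert all(s == {0, 1, 2} for s in res.node_states.values())

    def test_missing_tip_coding_raises(self):
        with pytest.raises(AsrError, match="C"):
            sankoff_parsimony(parse_newick("((A,B),C);"), coding_of(A=1, B=1))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_minimal_labelings(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, int(rng.integers(2, 7)))
        coding = random_coding(rng, t)
        res = sankoff_parsimony(t, coding)
        cost, mpr = enumerate_sankoff(t, coding)
        assert res.cost == cost
        assert res.node_states == mpr


class TestMkLoglik:
    def test_frozen_character_limit(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        ll = mk_loglik(t, coding_of(A=1, B=1, C=1), MkModel(3, "ER", np.array([1e-9])))
        assert ll == pytest.approx(math.log(1 / 3), abs=1e-6)

    def test_independence_limit_long_branches(self):
        t = parse_newick("(A:5000,B:5000);")
        ll = mk_loglik(t, coding_of(A=1, B=0), MkModel(3, "ER", np.array([1.0])))
        assert ll == pytest.approx(math.log(1 / 9), abs=1e-9)

    def test_non_positive_branch_length_rejected(self):
        t = parse_newick("(A:1,B:0);")
        with pytest.raises(AsrError):
            mk_loglik(t, coding_of(A=1, B=0), MkModel(3, "ER", np.array([0.1])))

    @pytest.mark.parametrize("seed", range(25))
    def test_pruning_matches_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        t = random_tree(rng, 5)
        coding = random_coding(rng, t)
        q = float(rng.uniform(0.01, 1.0))
        model = MkModel(3, "ER", np.array([q]))
        assert mk_loglik(t, coding, model) == pytest.approx(
            enumerate_loglik(t, coding, model), abs=1e-10
        )

    def test_sym_model_pruning_matches_enumeration(self):
        rng = np.random.default_rng(5)
        t = random_tree(rng, 4)
        coding = random_coding(rng, t)
        model = MkModel(3, "SYM", np.array([0.1, 0.3, 0.05]))
        assert mk_loglik(t, coding, model) == pytest.approx(
            enumerate_loglik(t, coding, model), abs=1e-10
        )

    def test_scale_invariance_of_qt(self):
        rng = np.random.default_rng(11)
        t = random_tree(rng, 6)
        coding = random_coding(rng, t)
        c = 7.3
        scaled = t.copy()
        for node in scaled.postorder():
            if node.parent is not None:
                node.length *= c
        ll1 = mk_loglik(t, coding, MkModel(3, "ER", np.array([0.2])))
        ll2 = mk_loglik(scaled, coding, MkModel(3, "ER", np.array([0.2 / c])))
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_state_permutation_symmetry(self):
        """Relabeling states while permuting the data identically leaves
        the ER likelihood unchanged."""
        rng = np.random.default_rng(21)
        t = random_tree(rng, 6)
        coding = random_coding(rng, t)
        perm = {0: 2, 1: 0, 2: 1}
        permuted = CharacterCoding(
            {k: frozenset(perm[s] for s in v) for k, v in coding.states.items()}
        )
        model = MkModel(3, "ER", np.array([0.15]))
        assert mk_loglik(t, coding, model) == pytest.approx(
            mk_loglik(t, permuted, model), abs=1e-12
        )


class TestFitMk:
    def test_constant_data_rate_at_lower_bound(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        model, ll, converged = fit_mk(t, coding_of(A=1, B=1, C=1, D=1))
        assert converged
        assert model.rates[0] < 1e-6
        assert ll == pytest.approx(math.log(1 / 3), abs=1e-4)

    def test_cherry_matches_grid_search(self):
        # two discordant tips: the likelihood (1 - e^{-6q})/9 rises to a
        # plateau, so compare attained likelihoods rather than rates
        t = parse_newick("(A:1,B:1);")
        coding = coding_of(A=1, B=0)
        model, ll, _ = fit_mk(t, coding)
        grid = np.exp(np.linspace(math.log(1e-6), math.log(100), 4000))
        lls = [mk_loglik(t, coding, MkModel(3, "ER", np.array([q]))) for q in grid]
        assert ll >= max(lls) - 1e-8
        assert ll == pytest.approx(math.log(1 / 9), abs=1e-4)

    def test_interior_mle_matches_grid_search(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        coding = coding_of(A=1, B=0, C=1, D=1)
        model, ll, _ = fit_mk(t, coding)
        grid = np.exp(np.linspace(math.log(1e-4), math.log(50), 6000))
        lls = [mk_loglik(t, coding, MkModel(3, "ER", np.array([q]))) for q in grid]
        q_grid = grid[int(np.argmax(lls))]
        assert model.rates[0] == pytest.approx(q_grid, rel=5e-3)
        assert ll >= max(lls) - 1e-10

    def test_rate_confidence_interval_brackets_mle(self):
        rng = np.random.default_rng(3)
        t = random_tree(rng, 8, min_len=1, max_len=10)
        coding = random_coding(rng, t, max_ambiguous=0)
        model, ll, _ = fit_mk(t, coding)
        lo, hi = rate_confidence_interval(t, coding, model, ll)
        assert lo <= model.rates[0] <= hi
        if lo > 1e-8:
            assert mk_loglik(t, coding, model.with_rates([lo])) == pytest.approx(
                ll - 1.92, abs=1e-5
            )


class TestMarginalAsr:
    def test_star_tree_all_uncertain_uniform(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        model = MkModel(3, "ER", np.array([0.3]))
        res = marginal_asr_ml(t, coding_of(A="?", B="?", C="?", D="?"), model)
        for v in res.node_states.values():
            assert np.allclose(v, 1 / 3, atol=1e-9)

    def test_monomorphic_root_probability_approaches_one(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        coding = coding_of(A=1, B=1, C=1, D=1)
        prev = 0.0
        for q in (0.3, 0.1, 0.01, 0.001):
            res = marginal_asr_ml(t, coding, MkModel(3, "ER", np.array([q])))
            p1 = res.node_states[t.root.id][1]
            assert p1 >= prev
            prev = p1
        assert prev > 0.999

    def test_singleton_tips_probability_one(self):
        rng = np.random.default_rng(2)
        t = random_tree(rng, 5)
        coding = random_coding(rng, t, max_ambiguous=0)
        res = marginal_asr_ml(t, coding, MkModel(3, "ER", np.array([0.2])))
        for tip in t.leaves():
            state = next(iter(coding[tip.label]))
            assert res.node_states[tip.id][state] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_posterior(self, seed):
        rng = np.random.default_rng(2000 + seed)
        t = random_tree(rng, 4)
        coding = random_coding(rng, t)
        q = float(rng.uniform(0.02, 0.8))
        model = MkModel(3, "ER", np.array([q]))
        res = marginal_asr_ml(t, coding, model)
        brute = enumerate_marginals(t, coding, model)
        for nid, v in brute.items():
            assert np.allclose(res.node_states[nid], v, atol=1e-10)

    def test_probability_vectors_sum_to_one(self):
        rng = np.random.default_rng(9)
        t = random_tree(rng, 12)
        coding = random_coding(rng, t)
        res = marginal_asr_ml(t, coding, MkModel(3, "ER", np.array([0.1])))
        for v in res.node_states.values():
            assert abs(v.sum() - 1.0) < 1e-9


class TestBayesAsr:
    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(4)
        t = random_tree(rng, 6, min_len=1, max_len=10)
        t.branch_mode = "timescaled"
        coding = random_coding(rng, t, max_ambiguous=0)
        mcmc = McmcSettings(iterations=2000, seed=99)
        a = bayes_asr(t, coding, mcmc)
        b = bayes_asr(t, coding, mcmc)
        for nid in a.node_states:
            assert np.array_equal(a.node_states[nid], b.node_states[nid])
        assert a.diagnostics == b.diagnostics

    def test_all_uncertain_recovers_flat_posterior(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t.branch_mode = "unit"
        res = bayes_asr(t, coding_of(A="?", B="?", C="?", D="?"),
                        McmcSettings(iterations=2000, seed=7))
        for v in res.node_states.values():
            assert np.allclose(v, 1 / 3, atol=1e-9)  # exact: data carry no signal

    def test_too_few_iterations_rejected(self):
        with pytest.raises(AsrError):
            McmcSettings(iterations=500, seed=1)

    def test_posteriors_close_to_ml_with_strong_data(self):
        """With many informative tips and a diffuse prior the Bayesian node
        posteriors should sit within 0.05 of the ML marginals at q-hat."""
        from paleoasr import simulate_mk_character, simulate_tree

        tree = simulate_tree(200, birth_rate=0.25, seed=42)
        states = simulate_mk_character(tree, q=0.05, root_state=1, seed=43)
        coding = CharacterCoding({k: frozenset({v}) for k, v in states.items()})
        model, _, _ = fit_mk(tree, coding)
        ml = marginal_asr_ml(tree, coding, model)
        mb = bayes_asr(tree, coding, McmcSettings(iterations=8000, thin=20, seed=44))
        assert mb.diagnostics["ess_rate"] > 100
        for nid in ml.node_states:
            assert np.max(np.abs(ml.node_states[nid] - mb.node_states[nid])) < 0.05
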