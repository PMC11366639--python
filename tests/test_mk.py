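"""Mk likelihood, fitting, model comparison and marginal reconstruction."""
import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from pvdevol import mk
from pvdevol.simulate import evolve_discrete_character, scale_tree_height, simulate_species_tree


def brute_force_loglik(tree, tips, q, cats=None):
    """Enumeration over all internal-node state assignments (flat root prior)."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    k = q.shape[0]
    cats = [1.0] if cats is None else list(cats)
    total = 0.0
    for r in cats:
        P = {id(n): expm(q * r * (n.edge.length or 0.0)) for n in nodes}
        for assign in itertools.product(range(k), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            for n in nodes:
                if n.is_leaf():
                    states[id(n)] = tips[n.taxon.label]
            like = 1.0 / k / len(cats)
            for n in nodes:
                if n.parent_node is not None:
                    like *= P[id(n)][states[id(n.parent_node)], states[id(n)]]
            total += like
    return np.log(total)


def brute_force_marginals(tree, tips, q, cats=None):
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    k = q.shape[0]
    cats = [1.0] if cats is None else list(cats)
    post = {id(n): np.zeros(k) for n in internal}
    for r in cats:
        P = {id(n): expm(q * r * (n.edge.length or 0.0)) for n in nodes}
        for assign in itertools.product(range(k), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            for n in nodes:
                if n.is_leaf():
                    states[id(n)] = tips[n.taxon.label]
            like = 1.0 / k / len(cats)
            for n in nodes:
                if n.parent_node is not None:
                    like *= P[id(n)][states[id(n.parent_node)], states[id(n)]]
            for n in internal:
                post[id(n)][states[id(n)]] += like
    out = {}
    for i, n in enumerate(nodes):
        if not n.is_leaf():
            label = n.label if n.label else f"node{i}"
            out[label] = post[id(n)] / post[id(n)].sum()
    return out


def random_instance(rng, max_tips=6):
    n = int(rng.integers(3, max_tips + 1))
    tree = simulate_species_tree(n, 1.0, seed=int(rng.integers(1, 2**31)))
    k = int(rng.integers(2, 5))
    param = "ER" if rng.random() < 0.5 else "SYM"
    spec = mk.MkModelSpec(k=k, parameterization=param)
    q = mk.build_q(spec, rng.uniform(0.1, 2.0, size=spec.n_rates))
    tips = {l.taxon.label: int(rng.integers(0, k)) for l in tree.leaf_node_iter()}
    return tree, tips, q


class TestBuildQ:
    def test_er_construction(self):
        q = mk.build_q(mk.MkModelSpec(k=4), [0.5])
        assert np.all(q[~np.eye(4, dtype=bool)] == 0.5)
        assert np.all(np.diag(q) == -1.5)

    def test_sym_with_equal_rates_is_er(self):
        er = mk.build_q(mk.MkModelSpec(k=3), [0.7])
        sym = mk.build_q(mk.MkModelSpec(k=3, parameterization="SYM"), [0.7] * 3)
        assert np.allclose(er, sym)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        spec = mk.MkModelSpec(k=5, parameterization="SYM")
        for _ in range(50):
            q = mk.build_q(spec, rng.uniform(0, 3, size=spec.n_rates))
            assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
            assert np.allclose(q, q.T)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mk.build_q(mk.MkModelSpec(k=3), [-0.1])

    def test_wrong_rate_count_rejected(self):
        with pytest.raises(ValueError):
            mk.build_q(mk.MkModelSpec(k=4, parameterization="SYM"), [0.5])


class TestLoglik:
    def test_single_branch_closed_form(self):
        for q_ in (0.1, 0.5, 2.0):
            for t in (0.05, 1.0, 4.0):
                tree = dendropy.Tree.get(data=f"(A:{t},B:0.0);", schema="newick")
                Q = mk.build_q(mk.MkModelSpec(k=2), [q_])
                got = mk.mk_loglik(tree, {"A": 0, "B": 0}, Q)
                expect = np.log(0.5 * (0.5 + 0.5 * np.exp(-2 * q_ * t)))
                assert got == pytest.approx(expect, abs=1e-10)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            tree, tips, q = random_instance(rng)
            assert mk.mk_loglik(tree, tips, q) == pytest.approx(
                brute_force_loglik(tree, tips, q), abs=1e-8
            )

    def test_rate_time_confounding(self):
        rng = np.random.default_rng(2)
        tree, tips, q = random_instance(rng)
        base = mk.mk_loglik(tree, tips, q)
        c = 3.7
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= c
        assert mk.mk_loglik(tree, tips, q / c) == pytest.approx(base, abs=1e-10)

    def test_missing_tip_equals_pruned_tree(self):
        tree = simulate_species_tree(5, 1.0, seed=9)
        q = mk.build_q(mk.MkModelSpec(k=3), [0.4])
        tips = {l.taxon.label: i % 3 for i, l in enumerate(tree.leaf_node_iter())}
        drop = sorted(tips)[0]
        tips_missing = dict(tips, **{drop: mk.MISSING})
        pruned = tree.clone(depth=1)
        pruned.prune_taxa_with_labels([drop])
        del tips[drop]
        assert mk.mk_loglik(tree, tips_missing, q) == pytest.approx(
            mk.mk_loglik(pruned, tips, q), abs=1e-10
        )

    def test_state_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        tree, tips, _ = random_instance(rng)
        q = mk.build_q(mk.MkModelSpec(k=3), [0.6])
        tips = {t: s % 3 for t, s in tips.items()}
        perm = {0: 2, 1: 0, 2: 1}
        relabeled = {t: perm[s] for t, s in tips.items()}
        assert mk.mk_loglik(tree, tips, q) == pytest.approx(
            mk.mk_loglik(tree, relabeled, q), abs=1e-10
        )

    def test_gamma_with_one_category_is_homogeneous(self):
        rng = np.random.default_rng(4)
        tree, tips, q = random_instance(rng)
        assert mk.mk_loglik(tree, tips, q, mk.gamma_category_rates(0.3, 1)) == pytest.approx(
            mk.mk_loglik(tree, tips, q)
        )

    def test_gamma_matches_enumeration(self):
        rng = np.random.default_rng(5)
        cats = mk.gamma_category_rates(0.6, 4)
        assert np.mean(cats) == pytest.approx(1.0, abs=1e-10)
        for _ in range(5):
            tree, tips, q = random_instance(rng, max_tips=5)
            assert mk.mk_loglik(tree, tips, q, cats) == pytest.approx(
                brute_force_loglik(tree, tips, q, cats), abs=1e-8
            )

    def test_bad_state_rejected(self):
        tree = simulate_species_tree(3, 1.0, seed=1)
        q = mk.build_q(mk.MkModelSpec(k=2), [0.5])
        tips = {l.taxon.label: 0 for l in tree.leaf_node_iter()}
        tips[sorted(tips)[0]] = 5
        with pytest.raises(ValueError):
            mk.mk_loglik(tree, tips, q)


class TestFit:
    def test_sym_attains_er_likelihood_when_truth_is_er(self):
        tree = scale_tree_height(simulate_species_tree(60, 1.0, seed=10), 1.0)
        tips, _ = evolve_discrete_character(tree, 3, 0.6, 0, seed=2)
        fer = mk.fit_mk(tree, tips, mk.MkModelSpec(k=3))
        fsym = mk.fit_mk(tree, tips, mk.MkModelSpec(k=3, parameterization="SYM"))
        assert fsym.log_likelihood >= fer.log_likelihood - 1e-6
        # and the ER optimum is reproduced by an equal-rates SYM matrix
        q_sym_equal = mk.build_q(
            mk.MkModelSpec(k=3, parameterization="SYM"), [fer.rates[0]] * 3
        )
        assert mk.mk_loglik(tree, tips, q_sym_equal) == pytest.approx(
            fer.log_likelihood, abs=1e-9
        )

    def test_aic_definition(self):
        tree = simulate_species_tree(20, 1.0, seed=3)
        tips, _ = evolve_discrete_character(tree, 2, 0.5, 0, seed=3)
        fit = mk.fit_mk(tree, tips, mk.MkModelSpec(k=2))
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)

    def test_monomorphic_tips_warn(self):
        tree = simulate_species_tree(8, 1.0, seed=4)
        tips = {l.taxon.label: 0 for l in tree.leaf_node_iter()}
        with pytest.warns(UserWarning):
            fit = mk.fit_mk(tree, tips, mk.MkModelSpec(k=2))
        assert fit.rates[0] <= 1e-6

    def test_compare_models_nesting_and_ranking(self):
        tree = scale_tree_height(simulate_species_tree(40, 1.0, seed=6), 1.0)
        tips, _ = evolve_discrete_character(tree, 3, 0.5, 0, seed=6)
        fer = mk.fit_mk(tree, tips, mk.MkModelSpec(k=3))
        fsym = mk.fit_mk(tree, tips, mk.MkModelSpec(k=3, parameterization="SYM"))
        comp = mk.compare_models([fer, fsym])
        assert [f.aic for f in comp.ranking] == sorted(f.aic for f in comp.ranking)
        (simple, complex_, stat, df), = comp.lrt
        assert (simple, complex_) == ("ER", "SYM")
        assert df == fsym.n_params - fer.n_params
        assert stat == pytest.approx(2 * (fsym.log_likelihood - fer.log_likelihood))
        assert stat >= -1e-6

    def test_single_fit_comparison(self):
        tree = simulate_species_tree(10, 1.0, seed=7)
        tips, _ = evolve_discrete_character(tree, 2, 0.5, 0, seed=7)
        comp = mk.compare_models([mk.fit_mk(tree, tips, mk.MkModelSpec(k=2))])
        assert len(comp.ranking) == 1 and comp.lrt == []


class TestMarginals:
    def test_probabilities_sum_to_one(self):
        tree = scale_tree_height(simulate_species_tree(50, 1.0, seed=8), 1.0)
        tips, _ = evolve_discrete_character(tree, 4, 0.5, 0, seed=8)
        q = mk.build_q(mk.MkModelSpec(k=4), [0.5])
        marg = mk.marginal_ancestral_states(tree, tips, q)
        assert len(marg) == 49
        for vec in marg.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((vec >= 0) & (vec <= 1))

    def test_frozen_character_limit(self):
        tree = simulate_species_tree(10, 1.0, seed=9)
        tips = {l.taxon.label: 1 for l in tree.leaf_node_iter()}
        q = mk.build_q(mk.MkModelSpec(k=3), [1e-9])
        marg = mk.marginal_ancestral_states(tree, tips, q)
        for vec in marg.values():
            assert vec[1] > 0.999

    def test_matches_enumeration_on_small_trees(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            tree, tips, q = random_instance(rng, max_tips=4)
            got = mk.marginal_ancestral_states(tree, tips, q)
            expect = brute_force_marginals(tree, tips, q)
            assert set(got) == set(expect)
            for node in got:
                assert np.abs(got[node] - expect[node]).max() < 1e-8

    def test_gamma_marginals_match_enumeration(self):
        rng = np.random.default_rng(11)
        cats = mk.gamma_category_rates(0.7, 3)
        tree, tips, q = random_instance(rng, max_tips=4)
        got = mk.marginal_ancestral_states(tree, tips, q, cats)
        expect = brute_force_marginals(tree, tips, q, cats)
        for node in got:
            assert np.abs(got[node] - expect[node]).max() < 1e-8


def test_states_from_labels_round_trip():
    labels = {"a": "II", "b": "XV", "c": "II", "d": mk.MISSING}
    states, levels = mk.states_from_labels(labels)
    assert levels == ["II", "XV"]
    assert states == {"a": 0, "b": 1, "c": 0, "d": mk.MISSING}
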