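"""Ancestral reconstruction: pruning likelihood, marginals, Fitch, events."""

import itertools

import dendropy
import numpy as np
import pytest

import mycosym as ms
from mycosym.asr import (
    asym_transition,
    asymmetry_lrt,
    count_events,
    fit_asym,
    fit_mk1,
    fitch_parsimony,
    marginal_states,
    mk1_transition,
)


def get_tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


# ---------------------------------------------------------------------------
# Transition matrices


def test_mk1_transition_closed_form():
    P = mk1_transition(1.0, 1.0)
    assert P[0, 1] == pytest.approx(0.5 * (1 - np.exp(-2)), abs=1e-12)
    assert np.allclose(P.sum(axis=1), 1.0)
    assert np.allclose(mk1_transition(0.0, 5.0), np.eye(2))
    assert np.allclose(mk1_transition(1.0, 1e6), 0.5)
    with pytest.raises(ValueError):
        mk1_transition(-1.0, 1.0)


def test_asym_transition_reduces_to_mk1():
    assert np.allclose(asym_transition(0.7, 0.7, 1.3), mk1_transition(0.7, 1.3))
    P = asym_transition(0.2, 0.9, 2.0)
    assert np.allclose(P.sum(axis=1), 1.0)
    # stationary distribution favors state 0 when loss rate dominates
    assert asym_transition(0.2, 0.9, 1e6)[0, 0] == pytest.approx(0.9 / 1.1, abs=1e-6)


# ---------------------------------------------------------------------------
# Likelihood oracle: exhaustive enumeration over internal states


def enumeration_loglik(tree, char, P_of_t, root_prior=(0.5, 0.5)):
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    total = 0.0
    for states in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, states))
        lik = root_prior[assign[tree.seed_node]]
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            s_par = assign[nd.parent_node]
            s = char[nd.taxon.label] if nd.is_leaf() else assign[nd]
            lik *= P_of_t(nd.edge.length)[s_par, s]
        total += lik
    return np.log(total)


@pytest.mark.parametrize("char", [
    {"a": 1, "b": 0, "c": 1},
    {"a": 0, "b": 0, "c": 1},
    {"a": 1, "b": 1, "c": 1},
])
def test_three_tip_likelihood_equals_enumeration(char):
    t = get_tree("((a:0.3,b:0.5):0.4,c:0.9);")
    from mycosym.asr import _prune_loglik

    for q in (0.1, 1.0, 3.0):
        P = lambda tt: mk1_transition(q, tt)
        assert _prune_loglik(t, char, P) == pytest.approx(
            enumeration_loglik(t, char, P), rel=1e-12
        )


def test_four_tip_marginals_equal_enumeration():
    t = get_tree("((a:0.2,b:0.4):0.3,(c:0.1,d:0.5):0.6);")
    char = {"a": 1, "b": 0, "c": 0, "d": 1}
    q = 0.8
    res = marginal_states(t, char, "mk1", rates=(q,))
    P = lambda tt: mk1_transition(q, tt)
    internals = [nd for nd in t.preorder_node_iter() if not nd.is_leaf()]
    from mycosym.asr import _node_label

    labels = {nd: _node_label(nd, i) for i, nd in enumerate(t.preorder_node_iter())}
    for target in internals:
        num = den = 0.0
        for states in itertools.product((0, 1), repeat=len(internals)):
            assign = dict(zip(internals, states))
            lik = 0.5
            for nd in t.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                s_par = assign[nd.parent_node]
                s = char[nd.taxon.label] if nd.is_leaf() else assign[nd]
                lik *= P(nd.edge.length)[s_par, s]
            den += lik
            if assign[target] == 1:
                num += lik
        assert res.node_probs[labels[target]][1] == pytest.approx(num / den, rel=1e-10)


def test_marginals_sum_to_one_and_trivial_case():
    t = get_tree("((a:1,b:1):1,c:2);")
    res = marginal_states(t, {"a": 1, "b": 1, "c": 1}, "mk1", rates=(0.05,))
    for p0, p1 in res.node_probs.values():
        assert p0 + p1 == pytest.approx(1.0)
    root_label = next(iter(res.node_probs))
    assert res.node_probs[root_label][1] > 0.5


def test_fit_matches_independent_reference_values():
    # expected rate/loglik computed with ape::ace (R) on this fixture and
    # frozen; ape reports the likelihood with an unweighted root sum, ours
    # uses equal priors, so the log likelihoods differ by exactly log(2)
    t = get_tree(
        "(((a:0.2,b:0.2):0.3,(c:0.1,d:0.4):0.2):0.3,"
        "((e:0.3,f:0.2):0.4,(g:0.5,h:0.1):0.2):0.1);"
    )
    char = {"a": 1, "b": 1, "c": 0, "d": 1, "e": 0, "f": 0, "g": 1, "h": 0}
    q, lnl = fit_mk1(t, char)
    assert q == pytest.approx(2.403485, abs=1e-4)
    assert lnl + np.log(2) == pytest.approx(-4.793742, abs=1e-5)
    q01, q10, lnl2 = fit_asym(t, char)
    assert q01 == pytest.approx(2.371532, abs=1e-3)
    assert q10 == pytest.approx(2.243422, abs=1e-3)
    assert lnl2 + np.log(2) == pytest.approx(-4.791633, abs=1e-5)


def test_monomorphic_character_flags_boundary():
    t = get_tree("((a:1,b:1):1,c:2);")
    with pytest.warns(UserWarning, match="lower bound"):
        q, lnl = fit_mk1(t, {"a": 1, "b": 1, "c": 1})
    assert q < 1e-6


def test_lnl_invariant_to_child_rotation():
    t1 = get_tree("((a:0.2,b:0.4):0.3,(c:0.1,d:0.5):0.6);")
    t2 = get_tree("((d:0.5,c:0.1):0.6,(b:0.4,a:0.2):0.3);")
    char = {"a": 1, "b": 0, "c": 0, "d": 1}
    assert fit_mk1(t1, char)[1] == pytest.approx(fit_mk1(t2, char)[1], rel=1e-9)


def test_asymmetry_lrt_identical_fits():
    t = get_tree(
        "(((a:0.2,b:0.2):0.3,(c:0.1,d:0.4):0.2):0.3,"
        "((e:0.3,f:0.2):0.4,(g:0.5,h:0.1):0.2):0.1);"
    )
    char = {"a": 1, "b": 1, "c": 0, "d": 1, "e": 0, "f": 0, "g": 1, "h": 0}
    lr, p, chosen = asymmetry_lrt(t, char)
    assert lr >= 0 and 0 < p <= 1
    assert chosen == "mk1"  # tiny LR on this fixture


def test_symmetric_simulations_choose_mk1():
    rng = np.random.default_rng(4)
    from mycosym.simulate import _yule_tree

    chosen_mk1 = 0
    n = 20
    for k in range(n):
        tree = _yule_tree(30, 1.0, rng)
        tns = tree.taxon_namespace
        for i, lf in enumerate(tree.leaf_node_iter()):
            lf.taxon = tns.new_taxon(label=f"t{i}")
        tree.update_taxon_namespace()
        char = ms.simulate.sim_mk1(tree, 0.5, seed=int(rng.integers(2**31)))
        if len(set(char.values())) < 2:
            chosen_mk1 += 1  # no signal either way; the test counts non-rejections
            continue
        _, _, chosen = asymmetry_lrt(tree, char)
        chosen_mk1 += chosen == "mk1"
    assert chosen_mk1 >= 0.9 * n


# ---------------------------------------------------------------------------
# Parsimony


def brute_force_parsimony(tree, char):
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = np.inf
    for states in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, states))
        changes = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            s = char[nd.taxon.label] if nd.is_leaf() else assign[nd]
            changes += s != assign[nd.parent_node]
        best = min(best, changes)
    return best


def test_fitch_trivial_and_balanced_cases():
    t = get_tree("((a:1,b:1):1,(c:1,d:1):1);")
    res = fitch_parsimony(t, {"a": 1, "b": 1, "c": 1, "d": 1})
    assert res.min_changes == 0 and res.n_gains == 0 and res.n_losses == 0
    res = fitch_parsimony(t, {"a": 1, "b": 0, "c": 1, "d": 0})
    assert res.min_changes == 2


def test_fitch_matches_bruteforce_on_random_trees(rng):
    from mycosym.simulate import _yule_tree

    for k in range(20):
        tree = _yule_tree(8, 1.0, rng)
        tns = tree.taxon_namespace
        for i, lf in enumerate(tree.leaf_node_iter()):
            lf.taxon = tns.new_taxon(label=f"t{i}")
        tree.update_taxon_namespace()
        char = {f"t{i}": int(rng.integers(2)) for i in range(8)}
        res = fitch_parsimony(tree, char)
        assert res.min_changes == brute_force_parsimony(tree, char)
        # ACCTRAN event total equals the parsimony score
        assert res.n_gains + res.n_losses == res.min_changes


def test_parsimony_score_bounded_by_state_counts(rng):
    from mycosym.simulate import _yule_tree

    tree = _yule_tree(10, 1.0, rng)
    tns = tree.taxon_namespace
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = tns.new_taxon(label=f"t{i}")
    tree.update_taxon_namespace()
    char = {f"t{i}": int(rng.integers(2)) for i in range(10)}
    res = fitch_parsimony(tree, char)
    ones = sum(char.values())
    assert res.min_changes <= min(ones, 10 - ones) or ones in (0, 10)


def test_count_events_single_flip():
    t = get_tree("((a:1,b:1):1,(c:1,d:1):1);")
    char = {"a": 1, "b": 1, "c": 0, "d": 0}
    res = fitch_parsimony(t, char)
    g, l, events = count_events(t, res)
    assert (g, l) == (1, 0) or (g, l) == (0, 1)  # root state ambiguity
    assert len(events) == 1


def test_ml_converges_to_parsimony_at_small_rate():
    t = ms.datasets.genus_tree()
    char = ms.datasets.glomeromycotina_character()
    ml = marginal_states(t, char, "mk1", rates=(1e-6,))
    pars = fitch_parsimony(t, char)
    g_ml, l_ml, _ = count_events(t, ml)
    assert (g_ml, l_ml) == (pars.n_gains, pars.n_losses)


def test_mk1_recovery_median_within_20pct():
    err, qs = ms.experiments.mk1_recovery(n_rep=30, n_tips=200, q_true=0.5, seed=17)
    assert err <= 0.2


def test_genus_tree_glomeromycotina_events():
    """Parsimony on the bundled genus tree: one gain, five losses."""
    t = ms.datasets.genus_tree()
    char = ms.datasets.glomeromycotina_character()
    res = fitch_parsimony(t, char)
    assert res.n_gains == 1
    assert res.n_losses == 5
    assert res.min_changes == 6
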