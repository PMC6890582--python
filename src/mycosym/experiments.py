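"""Calibration experiments: statistical checks run on synthetic data.

These routines back the validation suite and the reproduction script: each
generates data with :mod:`mycosym.simulate` under known truth, runs the
corresponding estimator, and reports a summary statistic (error rate,
recovery fraction, relative error).
"""

from __future__ import annotations

import numpy as np

from ._util import as_rng
from .asr import fit_mk1
from .gmyc import fit_single_threshold
from .simulate import _coalescent_subtree, sim_gmyc_tree, sim_mk1, _yule_tree

__all__ = [
    "gmyc_type1_error",
    "gmyc_recovery",
    "mk1_recovery",
    "adjusted_rand_index",
]


def _single_species_tree(n_tips, coal_rate, rng):
    """Pure-coalescent genealogy (one species) as an ultrametric tree."""
    import dendropy

    sub, depth = _coalescent_subtree(n_tips, coal_rate, rng)
    tns = dendropy.TaxonNamespace()
    for k, tip in enumerate(sub.leaf_iter()):
        tip.taxon = tns.new_taxon(label=f"t{k+1}")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    seed = tree.seed_node
    for ch in list(sub.child_nodes()):
        sub.remove_child(ch)
        seed.add_child(ch)
    tree.update_taxon_namespace()
    return tree


def gmyc_type1_error(n_sim: int = 100, n_tips: int = 20, coal_rate: float = 10.0,
                     alpha: float = 0.05, seed=None, estimate_exponents: bool = True):
    """Fraction of pure-coalescent (single species) trees wrongly split.

    Under the null there is no speciation/coalescence threshold; the LRT
    should reject at most ~alpha of the time.
    """
    rng = as_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        tree = _single_species_tree(n_tips, coal_rate, rng)
        fit = fit_single_threshold(tree, estimate_exponents=estimate_exponents)
        if fit.p_value <= alpha:
            rejections += 1
    return rejections / n_sim


def adjusted_rand_index(labels_a: dict, labels_b: dict) -> float:
    """ARI between two partitions given as {item: label} maps."""
    from sklearn.metrics import adjusted_rand_score

    items = sorted(labels_a)
    a = [labels_a[i] for i in items]
    b = [labels_b[i] for i in items]
    return float(adjusted_rand_score(a, b))


def _separation_factor(tree, truth):
    """Youngest speciation age / oldest true within-species MRCA age."""
    from collections import defaultdict

    from .gmyc import _node_ages

    ages, _ = _node_ages(tree)
    sp_tips = defaultdict(list)
    for lab, sp in truth.items():
        sp_tips[sp].append(lab)
    coal_max = 0.0
    for tips in sp_tips.values():
        if len(tips) > 1:
            coal_max = max(coal_max, ages[tree.mrca(taxon_labels=tips)])
    internal = sorted(ages[n] for n in tree.preorder_node_iter() if not n.is_leaf())
    spec_min = internal[-(len(sp_tips) - 1)]
    return spec_min / coal_max if coal_max > 0 else np.inf


def gmyc_recovery(n_sim: int = 50, n_species: int = 10, tips_per_species: int = 8,
                  lambda_spec: float = 1.0, coal_rate: float = 100.0,
                  ari_threshold: float = 0.9, seed=None,
                  estimate_exponents: bool = True, min_separation: float = 3.0):
    """Fraction of strongly separated simulations recovered (ARI >= 0.9).

    A replicate is *strongly separated* when its youngest speciation event is
    at least ``min_separation`` times older than its deepest within-species
    coalescence; an unconditioned Yule tree regularly produces a species pair
    younger than the coalescent scale, which no threshold model can separate,
    so replicates below the factor are redrawn.  Set ``min_separation=0`` to
    disable the conditioning.  Returns ``(fraction, aris)``.
    """
    rng = as_rng(seed)
    aris = []
    for _ in range(n_sim):
        for _try in range(200):
            tree, truth = sim_gmyc_tree(
                n_species, lambda_spec, tips_per_species, coal_rate,
                seed=int(rng.integers(2**31)),
            )
            if _separation_factor(tree, truth) >= min_separation:
                break
        fit = fit_single_threshold(tree, estimate_exponents=estimate_exponents)
        aris.append(adjusted_rand_index(truth, fit.partition))
    aris = np.array(aris)
    return float((aris >= ari_threshold).mean()), aris


def mk1_recovery(n_rep: int = 100, n_tips: int = 200, q_true: float = 0.5,
                 tree_depth_rate: float = 1.0, seed=None):
    """Median relative error of the Mk1 rate estimate on simulated characters.

    One Yule tree is simulated per replicate; a binary character evolves on it
    at the true rate and the rate is re-estimated by maximum likelihood.
    Returns ``(median_relative_error, estimates)``.
    """
    rng = as_rng(seed)
    qs = []
    for _ in range(n_rep):
        tree = _yule_tree(n_tips, tree_depth_rate, rng)
        tns = tree.taxon_namespace
        for k, lf in enumerate(tree.leaf_node_iter()):
            lf.taxon = tns.new_taxon(label=f"t{k+1}")
        tree.update_taxon_namespace()
        char = sim_mk1(tree, q_true, root_state=0, seed=int(rng.integers(2**31)))
        if len(set(char.values())) < 2:
            continue  # monomorphic draw carries no rate information
        q_hat, _ = fit_mk1(tree, char)
        qs.append(q_hat)
    qs = np.array(qs)
    med = float(np.median(qs))
    return abs(med - q_true) / q_true, qs
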