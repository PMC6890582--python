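"""Ancestral reconstruction of binary symbiosis characters on a genus tree.

Maximum likelihood uses the continuous-time Markov model of a binary
character: the symmetric one-parameter form (Mk1, a single rate q for gains
and losses) and the asymmetric two-parameter form (separate gain rate q01
and loss rate q10).  Likelihoods are computed with Felsenstein's pruning
algorithm under equal root-state priors; marginal state probabilities at
internal nodes come from the re-rooting construction.  An asymmetry
likelihood-ratio test (chi-square, df = 1) chooses between the two forms.

Maximum parsimony uses the two-pass Fitch algorithm with an ACCTRAN
resolution; gains (0->1) and losses (1->0) are counted per branch, and
branches whose assignment is ambiguous are also reported as a min-max range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar, minimize
from scipy.stats import chi2

__all__ = [
    "AsrResult",
    "mk1_transition",
    "asym_transition",
    "fit_mk1",
    "fit_asym",
    "asymmetry_lrt",
    "marginal_states",
    "fitch_parsimony",
    "count_events",
    "read_character_csv",
]

_Q_BOUNDS = (1e-9, 100.0)


def mk1_transition(q: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the symmetric binary Markov model.

    P(stay) = (1 + exp(-2qt))/2, P(change) = (1 - exp(-2qt))/2.
    """
    if q < 0 or t < 0:
        raise ValueError("q and t must be nonnegative")
    e = np.exp(-2.0 * q * t)
    same = 0.5 * (1.0 + e)
    diff = 0.5 * (1.0 - e)
    return np.array([[same, diff], [diff, same]])


def asym_transition(q01: float, q10: float, t: float) -> np.ndarray:
    """Transition matrix with separate gain (0->1) and loss (1->0) rates."""
    if q01 < 0 or q10 < 0 or t < 0:
        raise ValueError("rates and t must be nonnegative")
    Q = np.array([[-q01, q01], [q10, -q10]])
    return expm(Q * t)


@dataclass
class AsrResult:
    model: str  # "mk1" | "asym" | "parsimony"
    rates: tuple
    lnl: float | None
    node_probs: dict | None = None  # node id -> (P0, P1)
    state_sets: dict | None = None  # node id -> frozenset of states
    min_changes: int | None = None
    events: list = field(default_factory=list)  # (branch label, "gain"|"loss")
    n_gains: int | None = None
    n_losses: int | None = None
    gains_range: tuple | None = None
    losses_range: tuple | None = None


# ---------------------------------------------------------------------------
# Tree/character plumbing


def _validate(tree: dendropy.Tree, char: dict):
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("tip labels must be unique")
    missing = set(tips) - set(char)
    if missing:
        raise ValueError(f"character missing tip(s): {sorted(missing)}")
    for tip in tips:
        if char[tip] not in (0, 1):
            raise ValueError(f"state for {tip!r} must be 0 or 1")
    return tips


def _node_label(node, idx):
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"node{idx}"


def _prune_loglik(tree, char, P_of_t, root_prior=(0.5, 0.5)):
    """Felsenstein pruning: log likelihood given a branch-length->matrix map."""
    def partial(node):
        if node.is_leaf():
            L = np.zeros(2)
            L[char[node.taxon.label]] = 1.0
            return L, 0.0
        L = np.ones(2)
        logscale = 0.0
        for ch in node.child_nodes():
            Lc, sc = partial(ch)
            P = P_of_t(ch.edge.length or 0.0)
            L = L * (P @ Lc)
            logscale += sc
        s = L.sum()
        if s > 0:
            L = L / s
            logscale += np.log(s)
        return L, logscale

    L, logscale = partial(tree.seed_node)
    lik = float(np.dot(root_prior, L))
    if lik <= 0:
        return -np.inf
    return np.log(lik) + logscale


def fit_mk1(tree: dendropy.Tree, char: dict):
    """ML fit of the symmetric rate q.  Returns ``(q_hat, lnL)``.

    A monomorphic character drives q to the lower bound; this is flagged with
    a warning and the boundary value returned.
    """
    _validate(tree, char)

    def nll(logq):
        q = np.exp(logq)
        return -_prune_loglik(tree, char, lambda t: mk1_transition(q, t))

    res = minimize_scalar(
        nll, bounds=(np.log(_Q_BOUNDS[0]), np.log(_Q_BOUNDS[1])), method="bounded",
        options={"xatol": 1e-10},
    )
    q = float(np.exp(res.x))
    if q <= _Q_BOUNDS[0] * 10:
        warnings.warn("q at lower bound (character may be constant)")
    return q, float(-res.fun)


def fit_asym(tree: dendropy.Tree, char: dict):
    """ML fit of separate gain/loss rates.  Returns ``(q01, q10, lnL)``."""
    _validate(tree, char)
    q0, lnl0 = fit_mk1(tree, char)

    def nll(logq):
        q01, q10 = np.exp(logq)
        return -_prune_loglik(tree, char, lambda t: asym_transition(q01, q10, t))

    lb, ub = np.log(_Q_BOUNDS[0]), np.log(_Q_BOUNDS[1])
    start = np.clip(np.log([q0, q0]), lb, ub)
    best = None
    for s in (start, start + [0.5, -0.5], start + [-0.5, 0.5]):
        res = minimize(nll, s, method="L-BFGS-B", bounds=[(lb, ub)] * 2)
        if best is None or res.fun < best.fun:
            best = res
    q01, q10 = np.exp(best.x)
    lnl = float(-best.fun)
    if lnl < lnl0 - 1e-9:  # the symmetric model is nested; keep the better point
        lnl = lnl0
        q01 = q10 = q0
    return float(q01), float(q10), lnl


def asymmetry_lrt(tree: dendropy.Tree, char: dict, alpha: float = 0.05):
    """Asymmetry likelihood-ratio test: Mk1 vs the 2-rate model.

    Returns ``(LR, p, chosen_model)`` with the one-parameter model chosen
    when p > alpha.
    """
    q, lnl1 = fit_mk1(tree, char)
    q01, q10, lnl2 = fit_asym(tree, char)
    lr = 2.0 * (lnl2 - lnl1)
    if lr < -1e-6:
        raise ValueError("negative LR: optimizer failure")
    lr = max(lr, 0.0)
    p = float(chi2.sf(lr, 1))
    return lr, p, ("mk1" if p > alpha else "asym")


# ---------------------------------------------------------------------------
# Marginal reconstruction (re-rooting method)


def marginal_states(tree: dendropy.Tree, char: dict, model: str = "mk1",
                    rates=None) -> AsrResult:
    """Marginal state probabilities at every internal node.

    Implements the re-rooting construction: the marginal at a node combines
    the downward partial likelihoods of its subtree with the likelihood of
    the rest of the tree propagated from above; the root uses equal priors.
    """
    _validate(tree, char)
    if rates is None:
        if model == "mk1":
            q, lnl = fit_mk1(tree, char)
            rates = (q,)
        else:
            q01, q10, lnl = fit_asym(tree, char)
            rates = (q01, q10)
    if model == "mk1":
        P_of_t = lambda t: mk1_transition(rates[0], t)
    else:
        P_of_t = lambda t: asym_transition(rates[0], rates[1], t)

    down = {}

    def downward(node):
        if node.is_leaf():
            L = np.zeros(2)
            L[char[node.taxon.label]] = 1.0
        else:
            L = np.ones(2)
            for ch in node.child_nodes():
                downward(ch)
                P = P_of_t(ch.edge.length or 0.0)
                L = L * (P @ down[ch])
        s = L.sum()
        down[node] = L / s if s > 0 else L

    downward(tree.seed_node)

    up = {tree.seed_node: np.array([0.5, 0.5])}  # root prior

    def upward(node):
        for ch in node.child_nodes():
            # message to ch from the rest of the tree through node
            sib = np.ones(2)
            for other in node.child_nodes():
                if other is ch:
                    continue
                P = P_of_t(other.edge.length or 0.0)
                sib = sib * (P @ down[other])
            msg = up[node] * sib
            P = P_of_t(ch.edge.length or 0.0)
            u = P.T @ msg
            s = u.sum()
            up[ch] = u / s if s > 0 else u
            upward(ch)

    upward(tree.seed_node)

    probs = {}
    for idx, node in enumerate(tree.preorder_node_iter()):
        lab = _node_label(node, idx)
        if node.is_leaf():
            s = char[node.taxon.label]
            probs[lab] = (float(1 - s), float(s))
        else:
            m = up[node] * down[node]
            m = m / m.sum()
            probs[lab] = (float(m[0]), float(m[1]))
    lnl = _prune_loglik(tree, char, P_of_t)
    return AsrResult(model=model, rates=tuple(rates), lnl=float(lnl), node_probs=probs)


# ---------------------------------------------------------------------------
# Parsimony


def fitch_parsimony(tree: dendropy.Tree, char: dict) -> AsrResult:
    """Two-pass Fitch parsimony with ACCTRAN event counting.

    Returns the final (uppass) state sets, the minimum number of changes, and
    the gain/loss events of the ACCTRAN resolution; ambiguous branches widen
    the reported min-max ranges.
    """
    _validate(tree, char)
    down = {}
    changes = 0

    def downpass(node):
        nonlocal changes
        if node.is_leaf():
            down[node] = frozenset({char[node.taxon.label]})
            return
        sets = []
        for ch in node.child_nodes():
            downpass(ch)
            sets.append(down[ch])
        inter = frozenset.intersection(*sets)
        if inter:
            down[node] = inter
        else:
            down[node] = frozenset.union(*sets)
            changes += 1

    downpass(tree.seed_node)

    final = {tree.seed_node: down[tree.seed_node]}

    def uppass(node):
        for ch in node.child_nodes():
            if ch.is_leaf():
                final[ch] = down[ch]
            elif final[node] <= down[ch]:
                final[ch] = final[node]
            else:
                child_union = frozenset.union(*[down[c] for c in ch.child_nodes()])
                was_union = not frozenset.intersection(*[down[c] for c in ch.child_nodes()])
                if was_union:
                    final[ch] = down[ch] | final[node]
                else:
                    final[ch] = down[ch] | (final[node] & child_union)
            uppass(ch)

    uppass(tree.seed_node)

    # ACCTRAN resolution: resolve ambiguous nodes toward the parent's resolved
    # state only when that state is available, changes otherwise placed as
    # early (close to the root) as possible.
    resolved = {}

    def resolve(node, parent_state):
        s = final[node]
        if len(s) == 1:
            resolved[node] = next(iter(s))
        elif parent_state is not None and parent_state in s:
            resolved[node] = parent_state
        else:
            # root ambiguity without an outgroup: prefer absence (state 0)
            resolved[node] = 0 if 0 in s else next(iter(s))
        for ch in node.child_nodes():
            resolve(ch, resolved[node])

    resolve(tree.seed_node, None)

    events = []
    gains = losses = 0
    amb_extra = 0
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            continue
        ps, cs = resolved[node.parent_node], resolved[node]
        if ps != cs:
            kind = "gain" if cs == 1 else "loss"
            events.append((_node_label(node, idx), kind))
            gains += kind == "gain"
            losses += kind == "loss"
        elif len(final[node]) > 1:
            amb_extra += 1

    sets = {}
    for idx, node in enumerate(tree.preorder_node_iter()):
        sets[_node_label(node, idx)] = final[node]
    return AsrResult(
        model="parsimony",
        rates=(),
        lnl=None,
        state_sets=sets,
        min_changes=changes,
        events=events,
        n_gains=gains,
        n_losses=losses,
        gains_range=(max(gains - amb_extra, 0), gains + amb_extra),
        losses_range=(max(losses - amb_extra, 0), losses + amb_extra),
    )


def count_events(tree: dendropy.Tree, reconstruction: AsrResult):
    """Gain/loss totals and the per-branch event list of a reconstruction.

    For an ML reconstruction, node states are called at marginal probability
    0.5; for parsimony the ACCTRAN events are reported directly.
    """
    if reconstruction.model == "parsimony":
        return reconstruction.n_gains, reconstruction.n_losses, reconstruction.events
    if reconstruction.node_probs is None:
        raise ValueError("reconstruction has no node probabilities")
    labels = {}
    for idx, node in enumerate(tree.preorder_node_iter()):
        labels[node] = _node_label(node, idx)
    state = {
        node: (1 if reconstruction.node_probs[labels[node]][1] >= 0.5 else 0)
        for node in tree.preorder_node_iter()
    }
    events = []
    gains = losses = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        ps, cs = state[node.parent_node], state[node]
        if ps != cs:
            kind = "gain" if cs == 1 else "loss"
            events.append((labels[node], kind))
            gains += kind == "gain"
            losses += kind == "loss"
    return gains, losses, events


# ---------------------------------------------------------------------------
# I/O


def read_character_csv(path) -> dict:
    """Two-column CSV (taxon, state) -> {taxon: 0|1}."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("character CSV needs two columns (taxon, state)")
    out = {}
    for taxon, st in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[str(taxon)] = int(st)
    return out
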