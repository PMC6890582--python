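"""Single-threshold GMYC species delimitation on ultrametric trees.

The generalized mixed Yule-coalescent model places a threshold time t* on an
ultrametric tree: branching events older than t* are speciation events of a
Yule-type process with per-interval rate ``lambda1 * n^p1`` (n = number of
species lineages), events younger than t* are within-species coalescences
with summed rate ``lambda2 * sum_j [n_j (n_j - 1)/2]^p2`` over the clusters j
hanging below the threshold.  Inter-event waiting times are exponential with
the summed rate of the two processes.  The likelihood is maximized over the
candidate thresholds (the internal-node heights, where it is piecewise
constant) and compared against a null single-process model fitted to the
whole tree by a likelihood-ratio test (chi-square, df = 3 by default).

Trees must be rooted: the model needs directed time.

Also provided: the haplotype/clone dedup utilities used to prepare sequence
sets before delimitation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "GmycFit",
    "SequenceSet",
    "check_ultrametric",
    "branching_times",
    "fit_single_threshold",
    "likelihood_ratio_test",
    "delimit_with_singleton_policy",
    "dedup_haplotypes",
    "select_clone_representatives",
    "pairwise_identity",
]

_ULTRAMETRIC_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Tree plumbing


def check_ultrametric(tree: dendropy.Tree, rtol: float = _ULTRAMETRIC_RTOL) -> float:
    """Validate that all root-to-tip path lengths agree; returns tree depth.

    Raises ``ValueError`` reporting the maximum relative deviation otherwise.
    """
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if len(depths) < 3:
        raise ValueError("tree must have >= 3 tips")
    depths = np.array(depths)
    dmax = depths.max()
    dev = (dmax - depths.min()) / dmax if dmax > 0 else 0.0
    if dev > rtol:
        raise ValueError(f"tree is not ultrametric: max relative depth deviation {dev:.3g}")
    return float(dmax)


def _node_ages(tree: dendropy.Tree):
    """Age (time before the tips) of every node; tips forced to age 0."""
    depth = check_ultrametric(tree)
    ages = {}

    def walk(node, d):
        ages[node] = 0.0 if node.is_leaf() else max(depth - d, 0.0)
        for ch in node.child_nodes():
            walk(ch, d + (ch.edge.length or 0.0))

    walk(tree.seed_node, 0.0)
    return ages, depth


def branching_times(tree: dendropy.Tree):
    """Branching event times and lineage counts.

    Returns ``(times, counts)``: event times measured from the root (root at
    0, tips at tree depth) in increasing order, and the number of lineages
    present in each inter-event interval (``counts[k]`` lineages between
    ``times[k]`` and the next event or the tips).
    """
    ages, depth = _node_ages(tree)
    internal_ages = sorted(
        (ages[n] for n in tree.preorder_node_iter() if not n.is_leaf()), reverse=True
    )
    times = [depth - a for a in internal_ages]
    counts = list(range(2, len(internal_ages) + 2))
    return np.array(times), np.array(counts)


# ---------------------------------------------------------------------------
# Model fit


@dataclass
class GmycFit:
    threshold_age: float  # time before present; clusters coalesce younger than this
    lambda1: float
    p1: float
    lambda2: float
    p2: float
    logl: float
    logl_null: float
    null_params: tuple
    clusters: list  # lists of tip labels, each >= 2 tips
    singletons: list  # tip labels delimited alone
    n_entities: int
    lr: float = field(init=False)
    p_value: float = field(init=False)
    df: int = 3

    def __post_init__(self):
        self.lr, self.p_value = likelihood_ratio_test(self, df=self.df)

    @property
    def partition(self) -> dict:
        out = {}
        for k, cl in enumerate(self.clusters):
            for tip in cl:
                out[tip] = k
        base = len(self.clusters)
        for k, tip in enumerate(self.singletons):
            out[tip] = base + k
        return out


def _interval_data(tree):
    """Per-interval bookkeeping reused across thresholds.

    Returns event ages (desc), interval lengths (each interval ends at the
    next event; the last interval runs to the tips and is censored), total
    lineage counts per interval, and per-node cluster structure.
    """
    ages, depth = _node_ages(tree)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    order = np.argsort([-ages[n] for n in internal], kind="stable")
    nodes = [internal[i] for i in order]
    ev_ages = np.array([ages[n] for n in nodes])  # descending, root first
    bounds = np.concatenate([ev_ages, [0.0]])
    x = bounds[:-1] - bounds[1:]  # interval lengths; interval i starts at event i
    # lineages during interval i (just below event i): i+2
    n_lin = np.arange(2, len(nodes) + 2)
    return ages, depth, nodes, ev_ages, x, n_lin


def _cluster_counts(tree, ages, nodes, ev_ages, threshold_age):
    """For a threshold, the per-interval per-cluster pair counts.

    Entities are the lineages crossing the threshold.  Returns (K, pair count
    arrays per interval [ragged], cluster tip lists, singleton tips, and a
    speciation-interval mask giving the number of species lineages per
    interval).
    """
    eps = 1e-12 * (ages[tree.seed_node] or 1.0)
    # entity roots: nodes/tips whose subtree lies strictly below the threshold
    # but whose parent edge crosses it (or whose parent is a speciation node)
    def is_spec(node):
        return (not node.is_leaf()) and ages[node] >= threshold_age - eps

    entity_roots = []
    if not is_spec(tree.seed_node):
        entity_roots = [tree.seed_node]
    else:
        stack = [tree.seed_node]
        while stack:
            nd = stack.pop()
            for ch in nd.child_nodes():
                if is_spec(ch):
                    stack.append(ch)
                else:
                    entity_roots.append(ch)
    clusters, singles = [], []
    cluster_nodes = {}  # internal node -> cluster index
    for idx, er in enumerate(entity_roots):
        tips = [lf.taxon.label for lf in er.leaf_iter()]
        if len(tips) == 1:
            singles.append(tips[0])
        for nd in er.preorder_iter():
            if not nd.is_leaf():
                cluster_nodes[nd] = idx
        if len(tips) >= 2:
            clusters.append(tips)
    K = len(entity_roots)

    n_int = len(nodes)
    # species lineage count per interval: lineages until threshold, then K
    S = np.empty(n_int)
    # per-interval cluster lineage counts: cluster j has 1 + (#cluster nodes
    # with age > t) lineages at time t
    flat_pairs, flat_idx = [], []
    counts = {}  # entity index -> current lineage count (going root->tips)
    for i, nd in enumerate(nodes):
        # interval i lies just below event i (age ev_ages[i])
        if nd in cluster_nodes:
            j = cluster_nodes[nd]
            counts[j] = counts.get(j, 1) + 1
        below_threshold = ev_ages[i] < threshold_age - eps or not is_spec(nd)
        S[i] = K if nd in cluster_nodes else (i + 2 if not below_threshold else K)
        for j, c in counts.items():
            if c >= 2:
                flat_pairs.append(c * (c - 1) / 2.0)
                flat_idx.append(i)
    # event type: event ending interval i-1 is node i (age ev_ages[i]);
    # interval i's terminating event is nodes[i+1] (or the tips for the last)
    spec_mask = np.array([nd not in cluster_nodes for nd in nodes])
    return (
        K,
        np.array(flat_pairs),
        np.array(flat_idx, dtype=int),
        clusters,
        singles,
        S,
        spec_mask,
    )


def _neg_logl_factory(S, pairs, pair_idx, x, event_mask):
    """Negative log likelihood over (lambda1, lambda2, p1, p2).

    ``event_mask[i]`` is True when interval i ends in a branching event (the
    final interval to the tips is censored).
    """
    n_int = len(x)

    def nll(params):
        lam1, lam2, p1, p2 = params
        A = S**p1
        B = np.bincount(pair_idx, weights=pairs**p2, minlength=n_int) if len(pairs) else np.zeros(n_int)
        rate = lam1 * A + lam2 * B
        ev = rate[event_mask]
        if np.any(ev <= 0):
            return 1e12
        return float(-(np.log(ev).sum() - (rate * x).sum()))

    return nll


def _optimize(nll, x0, bounds):
    best = None
    for start in x0:
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def _fit_null(tree, estimate_exponents=True):
    """Single-process fit (one coalescent-type rate over the whole tree)."""
    ages, depth, nodes, ev_ages, x, n_lin = _interval_data(tree)
    pairs = n_lin * (n_lin - 1) / 2.0
    event_mask = np.ones(len(x), dtype=bool)
    event_mask[-1] = False  # the last interval ends at the contemporaneous tips

    def nll(params):
        lam, p = params
        rate = lam * pairs**p
        ev = rate[event_mask]
        if np.any(ev <= 0):
            return 1e12
        return float(-(np.log(ev).sum() - (rate * x).sum()))

    lam0 = event_mask.sum() / max((pairs * x).sum(), 1e-12)
    if estimate_exponents:
        res = _optimize(nll, [(lam0, 1.0), (lam0, 0.5)], [(1e-12, None), (0.0, 2.0)])
    else:
        res = _optimize(lambda q: nll((q[0], 1.0)), [(lam0,)], [(1e-12, None)])
        res.x = np.array([res.x[0], 1.0])
    return -res.fun, tuple(res.x)


def fit_single_threshold(tree: dendropy.Tree, estimate_exponents: bool = True,
                         df: int = 3) -> GmycFit:
    """Fit the single-threshold GMYC model, maximizing over thresholds.

    Candidate thresholds are the internal-node ages plus the degenerate
    "single cluster" threshold above the root (which nests the null model and
    guarantees a nonnegative likelihood ratio).  Rate exponents are estimated
    in [0, 2] by default; with ``estimate_exponents=False`` both are fixed
    at 1.
    """
    ages, depth, nodes, ev_ages, x, n_lin = _interval_data(tree)
    event_mask = np.ones(len(x), dtype=bool)
    event_mask[-1] = False
    logl_null, null_params = _fit_null(tree, estimate_exponents)

    candidates = [ev_ages[0] * 1.01 + 1e-9] + list(dict.fromkeys(ev_ages.tolist()))
    best = None
    n_events = event_mask.sum()
    for thr in candidates:
        K, pairs, pair_idx, clusters, singles, S, _ = _cluster_counts(
            tree, ages, nodes, ev_ages, thr
        )
        nll = _neg_logl_factory(S, pairs, pair_idx, x, event_mask)
        lam0 = n_events / max((S * x).sum(), 1e-12)
        mu0 = n_events / max(
            (np.bincount(pair_idx, weights=pairs, minlength=len(x)) * x).sum(), 1e-12
        ) if len(pairs) else 1.0
        if estimate_exponents:
            starts = [(lam0, mu0, 1.0, 1.0), (lam0 / 2, mu0 * 2, 0.5, 1.0)]
            bounds = [(0.0, None), (0.0, None), (0.0, 2.0), (0.0, 2.0)]
            res = _optimize(nll, starts, bounds)
        else:
            wrap = lambda q: nll((q[0], q[1], 1.0, 1.0))
            res = _optimize(wrap, [(lam0, mu0)], [(0.0, None), (0.0, None)])
            res.x = np.array([res.x[0], res.x[1], 1.0, 1.0])
        if res is None or not np.isfinite(res.fun):
            warnings.warn(f"optimizer failed at threshold {thr:.4g}; skipped")
            continue
        if best is None or -res.fun > best[0] + 1e-10:
            best = (-res.fun, thr, res.x, clusters, singles, K)
    if best is None:
        raise RuntimeError("all candidate thresholds failed to converge")
    logl, thr, params, clusters, singles, K = best
    logl = max(logl, logl_null)  # guard numerical slack: the null is nested
    return GmycFit(
        threshold_age=float(thr),
        lambda1=float(params[0]),
        p1=float(params[2]),
        lambda2=float(params[1]),
        p2=float(params[3]),
        logl=float(logl),
        logl_null=float(logl_null),
        null_params=null_params,
        clusters=clusters,
        singletons=singles,
        n_entities=K,
        df=df,
    )


def gmyc_log_likelihood(tree, threshold_age, lambda1, lambda2, p1=1.0, p2=1.0):
    """Log likelihood at a fixed threshold and fixed rates (no optimization).

    Exposed so the interval-density computation can be checked directly.
    """
    ages, depth, nodes, ev_ages, x, n_lin = _interval_data(tree)
    event_mask = np.ones(len(x), dtype=bool)
    event_mask[-1] = False
    K, pairs, pair_idx, clusters, singles, S, _ = _cluster_counts(
        tree, ages, nodes, ev_ages, threshold_age
    )
    nll = _neg_logl_factory(S, pairs, pair_idx, x, event_mask)
    return -nll((lambda1, lambda2, p1, p2))


def likelihood_ratio_test(fit: GmycFit, df: int = 3):
    """LR = 2(logL_gmyc - logL_null); p from chi-square with ``df``."""
    lr = 2.0 * (fit.logl - fit.logl_null)
    if lr < -1e-6:
        raise ValueError(f"negative likelihood ratio {lr:.3g}: optimizer failure")
    lr = max(lr, 0.0)
    return lr, float(chi2.sf(lr, df))


def delimit_with_singleton_policy(tree: dendropy.Tree, estimate_exponents: bool = True,
                                  df: int = 3) -> GmycFit:
    """Fit GMYC; if singletons are delimited, refit with them pruned.

    The pruned tips are carried through to the final report as singletons.
    Falls back to the first-pass fit (with a warning) when pruning would
    leave fewer than 3 tips.
    """
    first = fit_single_threshold(tree, estimate_exponents, df)
    if not first.singletons:
        return first
    keep = [t for t in tree.taxon_namespace if t.label not in set(first.singletons)]
    if len(keep) < 3:
        warnings.warn("pruning singletons would leave < 3 tips; keeping first-pass fit")
        return first
    pruned = tree.extract_tree_with_taxa(taxa=keep)
    pruned.purge_taxon_namespace()
    second = fit_single_threshold(pruned, estimate_exponents, df)
    second.singletons = sorted(set(second.singletons) | set(first.singletons))
    return second


# ---------------------------------------------------------------------------
# Sequence dedup utilities

_ALPHABET = set("ACGT-N")


@dataclass
class SequenceSet:
    ids: list
    seqs: list  # aligned, equal length
    mapping: dict = field(default_factory=dict)  # representative -> members

    def __post_init__(self):
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("sequences must be aligned to equal length")
        for s in self.seqs:
            bad = set(s.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"unexpected characters {sorted(bad)}")

    def __len__(self):
        return len(self.ids)

    @classmethod
    def from_fasta(cls, path) -> "SequenceSet":
        """Read an aligned FASTA file."""
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(ids, seqs)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)
        ]
        seqio_write(records, str(path), "fasta")


def _core_span(seq: str):
    s = seq.rstrip("-")
    lead = len(s) - len(s.lstrip("-"))
    return lead, len(s)


def dedup_haplotypes(seqs: SequenceSet) -> SequenceSet:
    """Collapse identical haplotypes (terminal gaps ignored) to one sequence.

    Identical haplotypes create zero branch lengths in time trees, which
    degrades delimitation; the representative kept is the first seen, and the
    mapping representative -> members is retained.
    """
    reps, rep_seqs, mapping = [], [], {}
    for sid, seq in zip(seqs.ids, seqs.seqs):
        s = seq.upper()
        lo, hi = _core_span(s)
        placed = False
        for k, (rid, rseq) in enumerate(zip(reps, rep_seqs)):
            rlo, rhi = _core_span(rseq)
            a, b = max(lo, rlo), min(hi, rhi)
            if a >= b:
                continue
            if s[a:b] == rseq[a:b]:
                mapping[rid].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            rep_seqs.append(s)
            mapping[sid] = [sid]
    return SequenceSet(reps, rep_seqs, mapping)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching aligned columns, gap-gap columns excluded."""
    num = den = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" and y == "-":
            continue
        den += 1
        if x == y:
            num += 1
    return num / den if den else 0.0


def select_clone_representatives(seqs: SequenceSet, threshold: float = 0.98) -> SequenceSet:
    """One representative per single-linkage group at identity > threshold.

    Within a sample's clone library, sequences sharing > 98% pairwise identity
    are treated as one clone group; the longest sequence (ties broken by input
    order) represents each group.
    """
    n = len(seqs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(seqs.seqs[i], seqs.seqs[j]) > threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    reps, rep_seqs, mapping = [], [], {}
    for members in sorted(groups.values(), key=lambda g: g[0]):
        lengths = [len(seqs.seqs[i].replace("-", "")) for i in members]
        best = members[int(np.argmax(lengths))]
        reps.append(seqs.ids[best])
        rep_seqs.append(seqs.seqs[best])
        mapping[seqs.ids[best]] = [seqs.ids[i] for i in members]
    return SequenceSet(reps, rep_seqs, mapping)
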