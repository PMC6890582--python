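"""Bipartite-network modularity by simulated annealing, with node roles.

The symbiosis network is scored with the standard (unipartite) modularity

    Q = sum_s [ l_s/L - (d_s/(2L))^2 ]

over modules s, where ``l_s`` is the number of edges inside s, ``d_s`` the
summed degree of its nodes and L the total edge count.  Optimization follows
the classic annealing scheme: at each temperature, f*S^2 single-node moves
and f*S collective moves (module merges and random splits) are proposed;
improvements are always accepted and worsenings with probability
exp(dQ / T).  Significance compares the observed Q against degree-preserving
bipartite edge-swap randomizations, each annealed with the same schedule.

Node roles use the participation coefficient PC (diversity of a node's links
across modules) and the within-module relative degree z; specialists are the
nodes with PC <= 0.62 and z <= 2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._util import as_rng
from .incidence import IncidenceMatrix

__all__ = [
    "SymbiosisGraph",
    "Partition",
    "RoleProfile",
    "AnnealSchedule",
    "graph_from_incidence",
    "modularity_q",
    "anneal_modularity",
    "modularity_significance",
    "bipartite_edge_swap",
    "node_roles",
    "specialist_fraction",
]


@dataclass
class SymbiosisGraph:
    """Undirected bipartite graph: plant and fungus nodes, one edge per link."""

    nodes: list  # labels
    side: np.ndarray  # 0 = plant, 1 = fungus
    edges: list  # (i, j) index pairs

    def __post_init__(self):
        self.side = np.asarray(self.side, dtype=int)
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if self.side[i] == self.side[j]:
                raise ValueError("edges must connect the two sides")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError("multi-edges are not allowed")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self):
        adj = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


def graph_from_incidence(mat: IncidenceMatrix) -> SymbiosisGraph:
    nodes = list(mat.row_labels) + list(mat.col_labels)
    nr = len(mat.row_labels)
    side = np.array([0] * nr + [1] * len(mat.col_labels))
    edges = [(i, nr + j) for i, j in zip(*np.nonzero(mat.M))]
    return SymbiosisGraph(nodes, side, edges)


@dataclass
class Partition:
    membership: np.ndarray  # node -> module index (0..n_modules-1, dense)
    q: float
    n_modules: int
    seed: int | None = None

    def modules(self):
        out = {}
        for i, m in enumerate(self.membership):
            out.setdefault(int(m), []).append(i)
        return out


@dataclass
class RoleProfile:
    node: object
    pc: float
    z: float | None
    role: str
    klass: str  # "specialist" | "generalist"


@dataclass
class AnnealSchedule:
    t0: float = 10.0
    cooling: float = 0.999
    iteration_factor: float = 1.0
    t_min: float = 1e-4
    stale_stop: int = 50  # stop after this many temperatures with no acceptance

    def __post_init__(self):
        if not (0 < self.cooling < 1) or self.t0 <= 0:
            raise ValueError("need 0 < cooling < 1 and t0 > 0")


def modularity_q(graph: SymbiosisGraph, membership) -> float:
    """Modularity of a node->module assignment."""
    L = graph.n_edges
    if L == 0:
        raise ValueError("graph has no edges")
    membership = np.asarray(membership)
    if len(membership) != graph.n_nodes:
        raise ValueError("partition must cover all nodes")
    mods = np.unique(membership)
    l_s = {m: 0 for m in mods}
    d_s = {m: 0 for m in mods}
    for i, j in graph.edges:
        if membership[i] == membership[j]:
            l_s[membership[i]] += 1
        d_s[membership[i]] += 1
        d_s[membership[j]] += 1
    return sum(l_s[m] / L - (d_s[m] / (2 * L)) ** 2 for m in mods)


class _AnnealState:
    """Incremental bookkeeping for the annealing moves (pure-python hot path)."""

    def __init__(self, graph: SymbiosisGraph, rng):
        self.adj = graph.adjacency()
        self.deg = [int(x) for x in graph.degrees()]
        self.L = graph.n_edges
        self.S = S = graph.n_nodes
        self.rng = rng
        self.mod = list(range(S))  # start: every node its own module
        self.d = list(self.deg)
        self.l = [0] * S
        self.members = [{v} for v in range(S)]
        self.occupied = list(range(S))
        self.pos = {m: i for i, m in enumerate(self.occupied)}
        self.free = []

    def q(self) -> float:
        L = self.L
        return sum(self.l[m] / L - (self.d[m] / (2 * L)) ** 2 for m in self.occupied)

    def _vacate(self, m):
        i = self.pos.pop(m)
        last = self.occupied.pop()
        if last != m:
            self.occupied[i] = last
            self.pos[last] = i
        self.free.append(m)

    def _occupy(self):
        m = self.free.pop()
        self.pos[m] = len(self.occupied)
        self.occupied.append(m)
        return m

    def single_delta(self, v, b):
        a = self.mod[v]
        kva = kvb = 0
        mod = self.mod
        for w in self.adj[v]:
            mw = mod[w]
            if mw == a:
                kva += 1
            elif mw == b:
                kvb += 1
        kv = self.deg[v]
        da, db = self.d[a], self.d[b]
        L = self.L
        dq = (kvb - kva) / L - (
            (da - kv) ** 2 + (db + kv) ** 2 - da * da - db * db
        ) / (4 * L * L)
        return dq, kva, kvb

    def apply_single(self, v, b, kva, kvb):
        a = self.mod[v]
        kv = self.deg[v]
        self.l[a] -= kva
        self.l[b] += kvb
        self.d[a] -= kv
        self.d[b] += kv
        self.mod[v] = b
        ma = self.members[a]
        ma.discard(v)
        self.members[b].add(v)
        if not ma:
            self._vacate(a)

    def merge_delta(self, a, b):
        if len(self.members[a]) > len(self.members[b]):
            a, b = b, a  # iterate the smaller side
        mod = self.mod
        e_ab = 0
        for v in self.members[a]:
            for w in self.adj[v]:
                if mod[w] == b:
                    e_ab += 1
        L = self.L
        return e_ab / L - self.d[a] * self.d[b] / (2 * L * L), e_ab

    def apply_merge(self, a, b, e_ab):
        if len(self.members[b]) > len(self.members[a]):
            a, b = b, a  # absorb the smaller module
        for v in self.members[b]:
            self.mod[v] = a
        self.members[a] |= self.members[b]
        self.members[b] = set()
        self.l[a] += self.l[b] + e_ab
        self.d[a] += self.d[b]
        self.l[b] = 0
        self.d[b] = 0
        self._vacate(b)

    def split_proposal(self, a):
        mem = self.members[a]
        if len(mem) < 2:
            return None
        mlist = sorted(mem)
        mask = self.rng.random(len(mlist)) < 0.5
        if mask.all() or not mask.any():
            return None
        half = {v for v, keep in zip(mlist, mask) if keep}
        mod = self.mod
        l_half = l_cross = d_half = 0
        for v in half:
            d_half += self.deg[v]
            for w in self.adj[v]:
                if mod[w] == a:
                    if w in half:
                        l_half += 1
                    else:
                        l_cross += 1
        l_half //= 2
        l_rest = self.l[a] - l_half - l_cross
        d_rest = self.d[a] - d_half
        L = self.L
        q_old = self.l[a] / L - (self.d[a] / (2 * L)) ** 2
        q_new = (l_half / L - (d_half / (2 * L)) ** 2) + (
            l_rest / L - (d_rest / (2 * L)) ** 2
        )
        return q_new - q_old, half, l_half, l_rest, d_half, d_rest

    def apply_split(self, a, half, l_half, l_rest, d_half, d_rest):
        b = self._occupy()
        for v in half:
            self.mod[v] = b
        self.members[a] -= half
        self.members[b] = set(half)
        self.l[a], self.d[a] = l_rest, d_rest
        self.l[b], self.d[b] = l_half, d_half


def anneal_modularity(graph: SymbiosisGraph, schedule: AnnealSchedule | None = None,
                      seed=None) -> Partition:
    """Maximize Q by simulated annealing; returns the best-seen partition.

    Starts from every node in its own module.  Deterministic for a fixed
    integer seed.
    """
    schedule = schedule or AnnealSchedule()
    rng = as_rng(seed)
    S = graph.n_nodes
    state = _AnnealState(graph, rng)
    t = schedule.t0
    n_single = max(1, int(schedule.iteration_factor * S * S))
    n_collective = max(1, int(schedule.iteration_factor * S))
    best_q = cur_q = state.q()
    best_mod = list(state.mod)
    stale = 0
    exp = math.exp
    while t >= schedule.t_min:
        accepted = 0
        vs = rng.integers(0, S, size=n_single)
        bsel = rng.random(n_single)
        us = rng.random(n_single)
        mod = state.mod
        occupied = state.occupied
        for k in range(n_single):
            v = vs[k]
            b = occupied[int(bsel[k] * len(occupied))]
            if b == mod[v]:
                continue
            dq, kva, kvb = state.single_delta(v, b)
            if dq >= 0 or us[k] < exp(dq / t):
                state.apply_single(v, b, kva, kvb)
                cur_q += dq
                accepted += 1
        for _ in range(n_collective):
            n_occ = len(occupied)
            if rng.random() < 0.5 and n_occ >= 2:
                i = int(rng.integers(n_occ))
                j = int(rng.integers(n_occ - 1))
                if j >= i:
                    j += 1
                a, b = occupied[i], occupied[j]
                dq, e_ab = state.merge_delta(a, b)
                if dq >= 0 or rng.random() < exp(dq / t):
                    state.apply_merge(a, b, e_ab)
                    cur_q += dq
                    accepted += 1
            else:
                a = occupied[int(rng.integers(n_occ))]
                prop = state.split_proposal(a)
                if prop is None:
                    continue
                dq, half, l_half, l_rest, d_half, d_rest = prop
                if dq >= 0 or rng.random() < exp(dq / t):
                    state.apply_split(a, half, l_half, l_rest, d_half, d_rest)
                    cur_q += dq
                    accepted += 1
        if cur_q > best_q:
            best_q = cur_q
            best_mod = list(state.mod)
        stale = 0 if accepted else stale + 1
        if stale >= schedule.stale_stop:
            break
        t *= schedule.cooling

    # densify module labels
    uniq, dense = np.unique(best_mod, return_inverse=True)
    return Partition(
        membership=dense,
        q=modularity_q(graph, dense),
        n_modules=len(uniq),
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# Degree-preserving randomization and significance


def bipartite_edge_swap(graph: SymbiosisGraph, rng, n_swaps: int | None = None) -> SymbiosisGraph:
    """Randomize links by side-respecting double edge swaps.

    Performs at least ``10 * L`` successful swaps (a-b, c-d) -> (a-d, c-b),
    rejecting any swap creating a multi-edge; degrees on both sides are
    preserved exactly.
    """
    L = graph.n_edges
    n_swaps = n_swaps if n_swaps is not None else 10 * L
    # orient every edge plant -> fungus
    edges = [(i, j) if graph.side[i] == 0 else (j, i) for i, j in graph.edges]
    edge_set = set(edges)
    done = tries = 0
    max_tries = 200 * n_swaps
    while done < n_swaps and tries < max_tries:
        tries += 1
        e1, e2 = rng.integers(L), rng.integers(L)
        (a, b), (c, d) = edges[e1], edges[e2]
        if a == c or b == d:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[e1], edges[e2] = (a, d), (c, b)
        done += 1
    return SymbiosisGraph(graph.nodes, graph.side, list(edge_set))


def modularity_significance(graph: SymbiosisGraph, n_rand: int = 100,
                            schedule: AnnealSchedule | None = None, seed=None,
                            q_obs: float | None = None):
    """One-way Z test of Q against degree-preserving randomizations.

    Each randomized graph is annealed with the same schedule; returns
    ``(Z, one_sided_p, null_qs)`` with p from the upper normal tail.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    rng = as_rng(seed)
    if q_obs is None:
        q_obs = anneal_modularity(graph, schedule, seed=int(rng.integers(2**31))).q
    null_qs = []
    for _ in range(n_rand):
        g = bipartite_edge_swap(graph, rng)
        null_qs.append(anneal_modularity(g, schedule, seed=int(rng.integers(2**31))).q)
    null_qs = np.array(null_qs)
    sd = float(null_qs.std(ddof=1))
    if sd == 0:
        return None, None, null_qs
    z = (q_obs - null_qs.mean()) / sd
    return float(z), float(norm.sf(z)), null_qs


# ---------------------------------------------------------------------------
# Node roles


def node_roles(graph: SymbiosisGraph, partition: Partition,
               pc_generalist: float = 0.62, z_hub: float = 2.5):
    """PC / within-module-degree role classification for every node.

    Hubs are nodes with z > 2.5; connector hubs additionally have PC > 0.30.
    Non-hubs: ultra-peripheral (PC <= 0.05), peripheral (PC <= 0.62),
    non-hub connector (PC > 0.62).  Nodes are generalists iff PC > 0.62 or
    z > 2.5.  In a singleton (or degree-constant) module z is undefined and
    treated as 0 for classification.
    """
    m = partition.membership
    adj = graph.adjacency()
    deg = graph.degrees()
    S = graph.n_nodes
    k_own = np.array([sum(1 for w in adj[v] if m[w] == m[v]) for v in range(S)])
    profiles = []
    # per-module mean/sd of within-module degree
    stats = {}
    for mod in np.unique(m):
        vals = k_own[m == mod]
        stats[mod] = (vals.mean(), vals.std(ddof=0))
    for v in range(S):
        k = deg[v]
        counts = {}
        for w in adj[v]:
            counts[m[w]] = counts.get(m[w], 0) + 1
        pc = 1.0 - sum((c / k) ** 2 for c in counts.values()) if k else 0.0
        mean, sd = stats[m[v]]
        z = (k_own[v] - mean) / sd if sd > 0 else None
        z_eff = 0.0 if z is None else z
        if z_eff > z_hub:
            role = "connector hub" if pc > 0.30 else "provincial hub"
        elif pc <= 0.05:
            role = "ultra-peripheral"
        elif pc <= pc_generalist:
            role = "peripheral"
        else:
            role = "non-hub connector"
        klass = "generalist" if (pc > pc_generalist or z_eff > z_hub) else "specialist"
        profiles.append(RoleProfile(graph.nodes[v], float(pc), z, role, klass))
    return profiles


def specialist_fraction(profiles) -> float:
    """Percent of nodes classified as specialists."""
    if not profiles:
        raise ValueError("empty profile list")
    return 100.0 * sum(1 for p in profiles if p.klass == "specialist") / len(profiles)
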