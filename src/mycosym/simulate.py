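"""Synthetic-data generators for every pipeline stage.

Each generator is deterministic under a fixed integer seed (one seeded numpy
Generator per call, no global state) and produces objects satisfying the
invariants of the consuming module: perfectly nested or block-modular
incidence matrices, occurrence tables with clade structure and dual
colonization, mixed Yule/coalescent ultrametric trees with a recorded true
species partition, and binary characters evolved under the symmetric Markov
model.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

from ._util import as_rng
from .asr import mk1_transition
from .incidence import IncidenceMatrix
from .records import SampleRegistry, OccurrenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "gen_nested",
    "gen_modular",
    "gen_records",
    "sim_gmyc_tree",
    "sim_mk1",
]


def gen_nested(n_rows: int, n_cols: int, fill: float) -> IncidenceMatrix:
    """Left-packed stair matrix, perfectly nested by construction.

    Row totals are strictly decreasing (and column totals likewise) whenever
    the requested fill permits; otherwise the closest feasible staircase is
    produced and logged.
    """
    if not 0 < fill <= 1:
        raise ValueError("fill must be in (0, 1]")
    target = int(round(fill * n_rows * n_cols))
    if n_cols >= n_rows:
        # strictly decreasing totals: r_i = (n_rows - i) + a_i with
        # non-increasing increments a_i <= n_cols - n_rows
        r = [n_rows - i for i in range(n_rows)]
        extra = target - sum(r)
        cap = n_cols - n_rows
        for i in range(n_rows):
            if extra <= 0:
                break
            a = min(cap, extra)
            r[i] += a
            extra -= a
    else:  # strict stairs infeasible: closest nonincreasing staircase
        r = [max(n_cols - i, 1) for i in range(n_rows)]
    if sum(r) != target:
        logger.info(
            "gen_nested: requested fill %.3f infeasible for strict stairs; using %d ones",
            fill,
            sum(r),
        )
    M = np.zeros((n_rows, n_cols), dtype=int)
    for i, ri in enumerate(r):
        M[i, :ri] = 1
    return IncidenceMatrix(
        M,
        [f"plant{i+1}" for i in range(n_rows)],
        [f"fungus{j+1}" for j in range(n_cols)],
        provenance={"generator": "gen_nested", "fill": fill},
    )


def gen_modular(n_blocks: int, block_rows: int, block_cols: int,
                p_in: float, p_out: float, seed=None) -> IncidenceMatrix:
    """Block-diagonal Bernoulli incidence with planted modules.

    Cells inside the diagonal blocks are 1 with probability ``p_in``, outside
    with ``p_out`` (< p_in).  Rows/columns left empty by the draw are redrawn
    (logged) so the matrix satisfies the incidence invariants.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = as_rng(seed)
    nr, nc = n_blocks * block_rows, n_blocks * block_cols
    P = np.full((nr, nc), p_out)
    for b in range(n_blocks):
        P[b * block_rows:(b + 1) * block_rows, b * block_cols:(b + 1) * block_cols] = p_in
    redraws = 0
    while True:
        M = (rng.random((nr, nc)) < P).astype(int)
        if M.sum(axis=1).all() and M.sum(axis=0).all():
            break
        redraws += 1
        if redraws > 1000:
            raise RuntimeError("could not draw a non-degenerate modular matrix")
    if redraws:
        logger.info("gen_modular: %d redraws due to empty rows/columns", redraws)
    return IncidenceMatrix(
        M,
        [f"plant{i+1}" for i in range(nr)],
        [f"fungus{j+1}" for j in range(nc)],
        provenance={
            "generator": "gen_modular",
            "n_blocks": n_blocks,
            "p_in": p_in,
            "p_out": p_out,
            "seed": seed,
            "true_row_blocks": [i // block_rows for i in range(nr)],
            "true_col_blocks": [j // block_cols for j in range(nc)],
        },
    )


_DEFAULT_CLADE_MIX = {  # sampling proportions of a broad liverwort survey
    "Haplomitriopsida": 0.107,
    "Marchantiopsida": 0.610,
    "Pelliidae": 0.283,
}
_COUNTRIES = ["NZ", "UK", "Chile", "Japan", "SouthAfrica", "USA"]


def gen_records(n_samples: int = 674, clade_mix=None, p_colonized: float = 0.25,
                p_dual: float = 0.25, taxon_pool_sizes=(31, 50),
                regional_endemism: float = 0.5, n_genera_per_clade: int = 6,
                seed=None):
    """Synthetic occurrence survey with clade structure and dual colonization.

    Samples are assigned clades (by ``clade_mix``), genera/species within the
    clade, and a country; each is colonized (one fungal detection from the
    focal Mucoromycotina pool) with probability ``p_colonized``, and colonized
    non-Haplomitriopsida samples additionally carry a Glomeromycotina taxon
    with probability ``p_dual``.  With probability ``regional_endemism`` a
    taxon is drawn from the sample's country-specific subpool, producing
    country-specific fungal taxa.  Taxa observed exactly once are flagged
    singletons.  Returns ``(SampleRegistry, [OccurrenceRecord])``.
    """
    rng = as_rng(seed)
    clade_mix = clade_mix or _DEFAULT_CLADE_MIX
    clades = list(clade_mix)
    probs = np.array([clade_mix[c] for c in clades], dtype=float)
    probs /= probs.sum()
    n_muc, n_glo = taxon_pool_sizes
    # split each lineage pool into a shared part and per-country endemic parts
    def pools(n, prefix):
        shared = [f"{prefix}{k+1}" for k in range(max(1, n // 2))]
        endemic = {}
        k = len(shared)
        per = max(1, (n - k) // len(_COUNTRIES))
        for c in _COUNTRIES:
            endemic[c] = [f"{prefix}{k+i+1}_{c}" for i in range(per)]
            k += per
        return shared, endemic

    muc_shared, muc_endemic = pools(n_muc, "epMT")
    glo_shared, glo_endemic = pools(n_glo, "epGT")

    rows = []
    raw = []
    for s in range(n_samples):
        clade = clades[rng.choice(len(clades), p=probs)]
        genus = f"{clade[:5]}Genus{rng.integers(n_genera_per_clade) + 1}"
        species = f"{genus} sp{rng.integers(3) + 1}"
        country = _COUNTRIES[rng.integers(len(_COUNTRIES))]
        sid = f"S{s+1:04d}"
        rows.append(
            {
                "sample_id": sid,
                "plant_species": species,
                "plant_genus": genus,
                "plant_clade": clade,
                "country": country,
                "subregion": "",
            }
        )
        if rng.random() < p_colonized:
            def draw(shared, endemic):
                if rng.random() < regional_endemism:
                    pool = endemic[country]
                else:
                    pool = shared
                return pool[rng.integers(len(pool))]

            raw.append((sid, draw(muc_shared, muc_endemic), "Mucoromycotina"))
            if clade != "Haplomitriopsida" and rng.random() < p_dual:
                raw.append((sid, draw(glo_shared, glo_endemic), "Glomeromycotina"))

    counts = {}
    for _, taxon, _lin in raw:
        counts[taxon] = counts.get(taxon, 0) + 1
    registry = SampleRegistry(pd.DataFrame(rows).set_index("sample_id"))
    records = [
        OccurrenceRecord(sid, taxon, lin, is_singleton=counts[taxon] == 1)
        for sid, taxon, lin in raw
    ]
    return registry, records


# ---------------------------------------------------------------------------
# Trees and characters


def _yule_tree(n_species: int, lam: float, rng) -> dendropy.Tree:
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    active = [root]
    t = 0.0
    end_time = {}
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * lam))
        nd = active.pop(int(rng.integers(k)))
        end_time[nd] = t
        c1, c2 = dendropy.Node(), dendropy.Node()
        nd.add_child(c1)
        nd.add_child(c2)
        active += [c1, c2]
    t_end = t + rng.exponential(1.0 / (n_species * lam))
    for nd in active:
        end_time[nd] = t_end
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = end_time[nd] - end_time[nd.parent_node]
    return tree


def _coalescent_subtree(n_tips: int, coal_rate: float, rng):
    """Kingman coalescent genealogy; returns (root node, depth)."""
    nodes = [(dendropy.Node(), 0.0) for _ in range(n_tips)]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0 * coal_rate))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha) = nodes.pop(j)
        (b, hb) = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - ha
        b.edge.length = t - hb
        nodes.append((parent, t))
    return nodes[0][0], nodes[0][1]


def sim_gmyc_tree(n_species: int = 10, lambda_spec: float = 1.0,
                  tips_per_species: int = 8, coal_rate: float = 100.0, seed=None):
    """Yule species tree with coalescent genealogies grafted below each tip.

    With ``coal_rate >> lambda_spec`` the within-species coalescences are
    much shallower than the speciation events, so a threshold model can
    recover the species.  All terminal branches are extended by the same
    amount so the output is ultrametric.  Returns ``(tree, truth)`` where
    ``truth`` maps tip label -> true species index.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = as_rng(seed)
    tree = _yule_tree(n_species, lambda_spec, rng)
    leaves = [lf for lf in tree.leaf_node_iter()]
    subtrees = []
    for _ in leaves:
        if tips_per_species > 1:
            subtrees.append(_coalescent_subtree(tips_per_species, coal_rate, rng))
        else:
            subtrees.append((None, 0.0))
    depth_max = max(d for _, d in subtrees)
    tns = dendropy.TaxonNamespace()
    truth = {}
    for sp, (leaf, (sub, d)) in enumerate(zip(leaves, subtrees)):
        pad = depth_max - d
        if sub is None:
            leaf.edge.length += depth_max
            label = f"sp{sp+1}_t1"
            leaf.taxon = tns.new_taxon(label=label)
            truth[label] = sp
            continue
        leaf.edge.length += pad
        for k, tip in enumerate(sub.leaf_iter()):
            label = f"sp{sp+1}_t{k+1}"
            tip.taxon = tns.new_taxon(label=label)
            truth[label] = sp
        for ch in list(sub.child_nodes()):
            sub.remove_child(ch)
            leaf.add_child(ch)
    tree.taxon_namespace = tns
    tree.update_taxon_namespace()
    return tree, truth


def sim_mk1(tree: dendropy.Tree, q: float, root_state: int = 0, seed=None) -> dict:
    """Evolve a binary character tipward under the symmetric Markov model.

    Returns {tip label: state}.
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    rng = as_rng(seed)
    state = {tree.seed_node: root_state}
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            P = mk1_transition(q, nd.edge.length or 0.0)
            s_par = state[nd.parent_node]
            state[nd] = int(rng.random() < P[s_par, 1])
        if nd.is_leaf():
            out[nd.taxon.label] = state[nd]
    return out
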