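"""End-to-end network pipeline: build -> connectance -> nestedness -> modularity.

Produces one summary row per network (combined and per-lineage), shaped like
the classic network-analysis results table: dimensions, association counts,
connectance, the three nestedness statistics with CE-null p values, and
annealed modularity with degree-preserving significance and node roles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .incidence import build_incidence, connectance_percent, to_edge_list
from .modularity import (
    AnnealSchedule,
    anneal_modularity,
    graph_from_incidence,
    modularity_significance,
    node_roles,
    specialist_fraction,
)
from .nestedness import nestedness_significance

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the conventional published ones
    (999 nestedness replicates, 100 modularity randomizations, annealing at
    T0=10 with 0.999 cooling and iteration factor 1)."""

    region_filter: str | None = None
    subregion_filter: str | None = None
    lineages: tuple = ("both", "Glomeromycotina", "Mucoromycotina")
    n_rep_nestedness: int = 999
    n_rand_modularity: int = 100
    nestedness_metrics: tuple = ("NODF_full", "NODF_rows", "NODF_cols", "T", "BR")
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _network_summary(mat, config, seed):
    graph = graph_from_incidence(mat)
    row = {
        "n_plants": mat.shape[0],
        "n_fungi": mat.shape[1],
        "n_associations": mat.n_associations,
        "n_links": mat.n_links,
        "connectance_pct": connectance_percent(mat),
    }
    for k, metric in enumerate(config.nestedness_metrics):
        res = nestedness_significance(
            mat, metric, n_rep=config.n_rep_nestedness, seed=seed + 17 * (k + 1),
            alpha=config.alpha,
        )
        row[metric] = res.observed
        row[f"{metric}_p"] = res.p
        row[f"{metric}_nested"] = res.nested
    part = anneal_modularity(graph, config.schedule, seed=seed + 101)
    z, p_mod, _ = modularity_significance(
        graph,
        n_rand=config.n_rand_modularity,
        schedule=config.schedule,
        seed=seed + 211,
        q_obs=part.q,
    )
    profiles = node_roles(graph, part)
    row.update(
        {
            "modularity_q": part.q,
            "n_modules": part.n_modules,
            "modularity_z": z,
            "modularity_p": p_mod,
            "modular": (p_mod is not None and p_mod <= config.alpha),
            "specialist_pct": specialist_fraction(profiles),
            "connector_hubs": sorted(
                str(pr.node) for pr in profiles if pr.role == "connector hub"
            ),
        }
    )
    return row, profiles


def run_pipeline(registry, records, config: RunConfig | None = None):
    """Run the full network pipeline for each configured lineage selection.

    Returns ``{"summary": DataFrame, "edges": {name: DataFrame},
    "roles": {name: [RoleProfile]}, "config": dict}``; when
    ``config.out_dir`` is set, also writes summary CSV/JSON, edge lists and
    a provenance record there.  Failures in one network stage are re-raised
    with the stage name after partial results are written.
    """
    config = config or RunConfig()
    rows, edge_lists, roles = {}, {}, {}
    for k, lineage in enumerate(config.lineages):
        name = "combined" if lineage == "both" else f"{lineage}-only"
        stage = f"network[{name}]"
        try:
            mat = build_incidence(
                registry,
                records,
                lineage_filter=lineage,
                region_filter=config.region_filter,
                subregion_filter=config.subregion_filter,
            )
            row, profs = _network_summary(mat, config, config.seed + 1000 * k)
        except Exception:
            _write_outputs(rows, edge_lists, config)
            logger.error("pipeline stage %s failed", stage)
            raise
        rows[name] = row
        edge_lists[name] = to_edge_list(mat)
        roles[name] = profs
    summary = pd.DataFrame(rows).T
    _write_outputs(rows, edge_lists, config)
    return {"summary": summary, "edges": edge_lists, "roles": roles,
            "config": config.provenance()}


def _write_outputs(rows, edge_lists, config):
    if not config.out_dir:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rows:
        pd.DataFrame(rows).T.to_csv(out / "network_summary.csv")
        with open(out / "network_summary.json", "w") as fh:
            json.dump(rows, fh, indent=2, default=str)
    for name, edges in edge_lists.items():
        edges.to_csv(out / f"edges_{name}.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(config.provenance(), fh, indent=2, default=str)
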