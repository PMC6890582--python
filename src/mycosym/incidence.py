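"""Bipartite incidence matrices: plant species x fungal taxa.

The binary matrix ``M`` has a 1 wherever at least one sample of a plant
species carried a fungal taxon; the parallel weight matrix ``W`` counts the
supporting samples (used for edge thickness in plots and exported with the
edge list).  Rows or columns that end up with no links are dropped at
construction so downstream statistics never see degenerate margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "build_incidence",
    "connectance",
    "connectance_percent",
    "pack",
    "read_incidence_tsv",
    "write_incidence_tsv",
    "to_edge_list",
]


@dataclass
class IncidenceMatrix:
    M: np.ndarray  # binary, rows = plants, cols = fungi
    row_labels: list
    col_labels: list
    W: np.ndarray | None = None  # sample support per link
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=int)
        if self.M.ndim != 2:
            raise ValueError("M must be 2-D")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("M must be binary")
        if self.W is None:
            self.W = self.M.copy()
        else:
            self.W = np.asarray(self.W, dtype=int)
            if ((self.W >= 1) != (self.M == 1)).any():
                raise ValueError("W must be >=1 exactly where M==1 and 0 elsewhere")
        if len(self.row_labels) != self.M.shape[0] or len(self.col_labels) != self.M.shape[1]:
            raise ValueError("label lengths must match matrix shape")

    @property
    def shape(self):
        return self.M.shape

    @property
    def fill(self) -> float:
        return float(self.M.sum()) / self.M.size

    @property
    def n_links(self) -> int:
        return int(self.M.sum())

    @property
    def n_associations(self) -> int:
        """Sample-level association count (sum of link weights)."""
        return int(self.W.sum())


def build_incidence(registry, records, lineage_filter="both", region_filter=None,
                    subregion_filter=None) -> IncidenceMatrix:
    """Build the plant-species x fungal-taxon matrix from occurrence records.

    ``lineage_filter`` is ``Mucoromycotina``, ``Glomeromycotina`` or ``both``;
    ``region_filter``/``subregion_filter`` restrict to samples from a country
    (and optional subregion).  Singleton taxa are kept as columns.
    """
    df = registry.samples
    keep_ids = set(df.index)
    if region_filter is not None:
        keep_ids &= set(df.index[df["country"] == region_filter])
    if subregion_filter is not None:
        keep_ids &= set(df.index[df["subregion"] == subregion_filter])

    sel = [
        r
        for r in records
        if r.sample_id in keep_ids
        and (lineage_filter == "both" or r.fungal_lineage == lineage_filter)
    ]
    if not sel:
        raise ValueError("no records match the requested filters")

    weights: dict[tuple[str, str], int] = {}
    for r in sel:
        key = (registry.species_of(r.sample_id), r.fungal_taxon)
        weights[key] = weights.get(key, 0) + 1

    rows = sorted({k[0] for k in weights})
    cols = sorted({k[1] for k in weights})
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    W = np.zeros((len(rows), len(cols)), dtype=int)
    for (sp, tx), w in weights.items():
        W[ri[sp], ci[tx]] = w
    return IncidenceMatrix(
        (W > 0).astype(int),
        rows,
        cols,
        W=W,
        provenance={
            "lineage_filter": lineage_filter,
            "region_filter": region_filter,
            "subregion_filter": subregion_filter,
        },
    )


def connectance(mat: IncidenceMatrix | np.ndarray) -> float:
    """Realized fraction of all possible plant-fungus links."""
    M = mat.M if isinstance(mat, IncidenceMatrix) else np.asarray(mat)
    if M.size == 0:
        raise ValueError("empty matrix")
    return float(M.sum()) / M.size


def connectance_percent(mat) -> int:
    from ._util import round_half_up

    return round_half_up(100.0 * connectance(mat))


def pack(mat: IncidenceMatrix | np.ndarray):
    """Order rows and columns by descending marginal totals (stable on ties).

    The conventional "most common in the top left" packing required before
    nestedness calculations.  Idempotent.
    """
    if isinstance(mat, IncidenceMatrix):
        M = mat.M
        ri = np.argsort(-M.sum(axis=1), kind="stable")
        ci = np.argsort(-M.sum(axis=0), kind="stable")
        return IncidenceMatrix(
            M[np.ix_(ri, ci)],
            [mat.row_labels[i] for i in ri],
            [mat.col_labels[j] for j in ci],
            W=mat.W[np.ix_(ri, ci)],
            provenance=dict(mat.provenance, packed=True),
        )
    M = np.asarray(mat, dtype=int)
    ri = np.argsort(-M.sum(axis=1), kind="stable")
    ci = np.argsort(-M.sum(axis=0), kind="stable")
    return M[np.ix_(ri, ci)]


# ---------------------------------------------------------------------------
# I/O


def write_incidence_tsv(mat: IncidenceMatrix, path) -> None:
    pd.DataFrame(mat.M, index=mat.row_labels, columns=mat.col_labels).to_csv(path, sep="\t")


def read_incidence_tsv(path) -> IncidenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IncidenceMatrix(df.to_numpy(dtype=int), list(df.index), list(df.columns))


def to_edge_list(mat: IncidenceMatrix) -> pd.DataFrame:
    """Edge-list export (plant, fungus, weight) for plotting."""
    rows = []
    for i, plant in enumerate(mat.row_labels):
        for j, fungus in enumerate(mat.col_labels):
            if mat.M[i, j]:
                rows.append({"plant": plant, "fungus": fungus, "weight": int(mat.W[i, j])})
    return pd.DataFrame(rows, columns=["plant", "fungus", "weight"])
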