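"""Occurrence records: the sample-level data model of a plant-fungus survey.

A survey consists of two tables.  The *sample registry* lists every plant
sample collected (colonized or not) with its taxonomy and provenance; the
*detection table* lists one row per (sample, fungal taxon) detection.  Keeping
uncolonized samples first-class is essential: detection rates need true
denominators, which cannot be recovered from detections alone.

Fungal taxa are species-delimitation clusters ("epMT" for Mucoromycotina,
"epGT" for Glomeromycotina) or singleton sequence identifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

PLANT_CLADES = ("Haplomitriopsida", "Marchantiopsida", "Pelliidae")
FUNGAL_LINEAGES = ("Mucoromycotina", "Glomeromycotina")

__all__ = [
    "OccurrenceRecord",
    "SampleRegistry",
    "DetectionSummary",
    "SchemaError",
    "read_records",
    "write_records",
    "summarize_detection",
    "count_cocolonized",
    "taxa_per_colonized_sample",
    "PLANT_CLADES",
    "FUNGAL_LINEAGES",
]


class SchemaError(ValueError):
    """Raised when an input table does not match the documented schema."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One detection of a fungal taxon in one plant sample."""

    sample_id: str
    fungal_taxon: str
    fungal_lineage: str
    is_singleton: bool = False

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        if self.fungal_lineage not in FUNGAL_LINEAGES:
            raise SchemaError(
                f"unknown fungal_lineage {self.fungal_lineage!r}; "
                f"expected one of {FUNGAL_LINEAGES}"
            )


@dataclass
class SampleRegistry:
    """sample_id -> (plant_species, plant_genus, plant_clade, region, subregion)."""

    samples: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("plant_species", "plant_genus", "plant_clade", "country")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.samples.columns:
                raise SchemaError(f"sample table is missing required column {col!r}")
        if "subregion" not in self.samples.columns:
            self.samples = self.samples.assign(subregion="")
        bad = set(self.samples["plant_clade"]) - set(PLANT_CLADES)
        if bad:
            raise SchemaError(
                f"unknown plant_clade value(s) {sorted(bad)}; expected {PLANT_CLADES}"
            )
        if self.samples.index.has_duplicates:
            raise SchemaError("duplicate sample_id in sample table")

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample_id) -> bool:
        return sample_id in self.samples.index

    def clade_of(self, sample_id: str) -> str:
        return self.samples.at[sample_id, "plant_clade"]

    def species_of(self, sample_id: str) -> str:
        return self.samples.at[sample_id, "plant_species"]


@dataclass
class DetectionSummary:
    """Detection count/rate for one grouping of samples."""

    group: str
    n_samples: int
    n_colonized: int
    rate: int  # integer percent, round half up
    n_species: int
    species_is_minimum: bool = False  # True when genus-only IDs make it a ">= n"

    def __post_init__(self):
        if not 0 <= self.n_colonized <= self.n_samples:
            raise ValueError("0 <= n_colonized <= n_samples violated")


# ---------------------------------------------------------------------------
# I/O


def read_records(samples_csv, detections_csv):
    """Read a survey from its two CSV tables.

    ``samples.csv``: sample_id, plant_species, plant_genus, plant_clade,
    country, subregion.  ``detections.csv``: sample_id, fungal_taxon,
    fungal_lineage, is_singleton.  Returns ``(SampleRegistry, [OccurrenceRecord])``.
    Duplicate (sample_id, fungal_taxon) rows are deduplicated with a warning;
    unknown clade or lineage values raise :class:`SchemaError`.
    """
    sdf = pd.read_csv(samples_csv, dtype=str).fillna("")
    if "sample_id" not in sdf.columns:
        raise SchemaError("sample table is missing required column 'sample_id'")
    registry = SampleRegistry(sdf.set_index("sample_id"))

    ddf = pd.read_csv(detections_csv, dtype=str).fillna("")
    for col in ("sample_id", "fungal_taxon", "fungal_lineage"):
        if col not in ddf.columns:
            raise SchemaError(f"detection table is missing required column {col!r}")
    if "is_singleton" not in ddf.columns:
        ddf["is_singleton"] = "false"

    ndup = ddf.duplicated(subset=["sample_id", "fungal_taxon"]).sum()
    if ndup:
        warnings.warn(f"dropped {ndup} duplicate (sample_id, fungal_taxon) rows")
        ddf = ddf.drop_duplicates(subset=["sample_id", "fungal_taxon"])

    records = []
    for row in ddf.itertuples(index=False):
        if row.sample_id not in registry:
            raise SchemaError(f"detection references unknown sample_id {row.sample_id!r}")
        records.append(
            OccurrenceRecord(
                sample_id=row.sample_id,
                fungal_taxon=row.fungal_taxon,
                fungal_lineage=row.fungal_lineage,
                is_singleton=str(row.is_singleton).strip().lower() in ("1", "true", "yes"),
            )
        )
    logger.info("read %d samples, %d detection records", len(registry), len(records))
    return registry, records


def write_records(registry: SampleRegistry, records, samples_csv, detections_csv) -> None:
    """Inverse of :func:`read_records` (same two-table schema)."""
    registry.samples.reset_index(names="sample_id").to_csv(samples_csv, index=False)
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "fungal_taxon": r.fungal_taxon,
                "fungal_lineage": r.fungal_lineage,
                "is_singleton": r.is_singleton,
            }
            for r in records
        ],
        columns=["sample_id", "fungal_taxon", "fungal_lineage", "is_singleton"],
    ).to_csv(detections_csv, index=False)


# ---------------------------------------------------------------------------
# Summaries


def _colonized_ids(records, lineage):
    return {r.sample_id for r in records if r.fungal_lineage == lineage}


def _species_count(species: pd.Series):
    """Count distinct species; genus-only IDs (species == genus or endswith ' sp.')
    contribute one 'minimum' species per genus and set the >= flag."""
    spp = set()
    genus_only = set()
    for sp in species:
        s = str(sp)
        if s.endswith(" sp.") or s.endswith("_sp") or s == "":
            genus_only.add(s)
        else:
            spp.add(s)
    n = len(spp) + len(genus_only)
    return n, bool(genus_only)


def summarize_detection(registry, records, group_by="all", lineage="Mucoromycotina"):
    """Per-group detection summaries (one :class:`DetectionSummary` per group).

    ``group_by`` is one of ``all``, ``clade``, ``genus``.  Rates are integer
    percent, rounded half up, matching the printed-table convention.  Groups
    with zero samples are omitted.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    if group_by not in ("all", "clade", "genus"):
        raise ValueError(f"group_by must be all|clade|genus, got {group_by!r}")
    colonized = _colonized_ids(records, lineage)
    df = registry.samples
    if group_by == "all":
        groups = [("All samples", df)]
    else:
        key = "plant_clade" if group_by == "clade" else "plant_genus"
        groups = [(name, sub) for name, sub in df.groupby(key, sort=True)]

    out = []
    for name, sub in groups:
        n = len(sub)
        if n == 0:
            continue
        ncol = sum(1 for sid in sub.index if sid in colonized)
        nsp, is_min = _species_count(sub["plant_species"])
        out.append(
            DetectionSummary(
                group=str(name),
                n_samples=n,
                n_colonized=ncol,
                rate=round_half_up(100.0 * ncol / n),
                n_species=nsp,
                species_is_minimum=is_min,
            )
        )
    return out


def count_cocolonized(registry, records):
    """Samples hosting both fungal lineages at once.

    Returns ``(n_samples, n_species, n_genera)`` where species/genus counts
    are of the distinct species/genera among co-colonized samples.
    """
    muc = _colonized_ids(records, "Mucoromycotina")
    glo = _colonized_ids(records, "Glomeromycotina")
    both = muc & glo
    if not both:
        return 0, 0, 0
    sub = registry.samples.loc[sorted(both)]
    nsp, _ = _species_count(sub["plant_species"])
    return len(both), nsp, sub["plant_genus"].nunique()


def taxa_per_colonized_sample(registry, records, clade, lineage="Mucoromycotina"):
    """Distinct non-singleton taxa per colonized sample within a clade.

    A sampling-effort-corrected diversity ratio, reported to one decimal
    (half-up).  Raises if the clade has no colonized sample.
    """
    if clade not in PLANT_CLADES:
        raise ValueError(f"unknown clade {clade!r}")
    ids = set(registry.samples.index[registry.samples["plant_clade"] == clade])
    in_clade = [r for r in records if r.sample_id in ids and r.fungal_lineage == lineage]
    colonized = {r.sample_id for r in in_clade}
    if not colonized:
        raise ValueError(f"no colonized samples in clade {clade}")
    taxa = {r.fungal_taxon for r in in_clade if not r.is_singleton}
    return round_half_up(len(taxa) / len(colonized), decimals=1)
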