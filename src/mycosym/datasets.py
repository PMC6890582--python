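"""Bundled example data for the liverwort-Mucoromycotina symbiosis.

Two kinds of fixture are provided, both stored as plain text in this module:

* ``survey_counts`` / ``survey_registry`` — genus-level detection counts of a
  worldwide survey of Mucoromycotina colonization in 674 liverwort samples
  (three clades: Haplomitriopsida, Marchantiopsida, Pelliidae).  The counts
  are real published summary values; :func:`survey_registry` expands them
  into a per-sample registry + detection table whose group-level counts
  reproduce the summary exactly.  Sample-to-taxon assignments within each
  clade are synthetic (cyclic over the clade's delimited-taxon pool), so the
  expansion supports group summaries and diversity ratios, not per-sample
  network structure.

* ``genus_tree`` / ``glomeromycotina_character`` / ``mucoromycotina_character``
  — a hand-encoded genus-level liverwort phylogeny (rooted on the moss
  outgroup Takakia) with nominal, synthetic branch lengths of 1.0, plus
  binary presence/absence scorings of the two fungal symbiont lineages per
  genus.  The topology is a curated consensus of multi-marker liverwort
  phylogenies; it feeds worked examples and tests of the ancestral
  reconstruction code.
"""

from __future__ import annotations

import io

import dendropy
import pandas as pd

from .records import OccurrenceRecord, SampleRegistry

__all__ = [
    "survey_counts",
    "survey_registry",
    "genus_tree",
    "glomeromycotina_character",
    "mucoromycotina_character",
]

# genus, clade, n_samples, n_colonized (Mucoromycotina), n_species
_SURVEY = """\
genus,clade,n_samples,n_colonized,n_species
Treubia,Haplomitriopsida,56,42,2
Haplomitrium,Haplomitriopsida,16,8,5
Neohodgsonia,Marchantiopsida,8,3,1
Lunularia,Marchantiopsida,36,9,1
Marchantia,Marchantiopsida,63,0,10
Preissia,Marchantiopsida,9,0,1
Asterella,Marchantiopsida,81,24,12
Cryptomitrium,Marchantiopsida,6,0,2
Mannia,Marchantiopsida,5,0,1
Plagiochasma,Marchantiopsida,48,6,2
Reboulia,Marchantiopsida,9,0,1
Athalamia,Marchantiopsida,1,0,1
Clevea,Marchantiopsida,2,0,1
Sauteria,Marchantiopsida,2,0,1
Conocephalum,Marchantiopsida,30,0,3
Cyathodium,Marchantiopsida,7,0,3
Corsinia,Marchantiopsida,4,0,1
Oxymitra,Marchantiopsida,1,0,1
Targionia,Marchantiopsida,34,10,1
Monoclea,Marchantiopsida,34,4,2
Dumortiera,Marchantiopsida,31,0,1
Noteroclada,Pelliidae,4,0,1
Pellia,Pelliidae,16,1,3
Calycularia,Pelliidae,10,3,1
Sewardiella,Pelliidae,3,2,1
Allisonia,Pelliidae,7,1,1
Fossombronia,Pelliidae,116,49,15
Phyllothallia,Pelliidae,3,0,1
Moerckia,Pelliidae,1,1,1
Hymenophyton,Pelliidae,4,0,1
Jensenia,Pelliidae,1,0,1
Pallavicinia,Pelliidae,5,1,1
Podomitrium,Pelliidae,2,0,1
Symphyogyna,Pelliidae,19,1,4
"""

#: number of delimited (non-singleton) Mucoromycotina taxa detected per clade
_EPMT_PER_CLADE = {"Haplomitriopsida": 9, "Marchantiopsida": 15, "Pelliidae": 22}


def survey_counts() -> pd.DataFrame:
    """Genus-level survey summary (samples, colonized, species per genus)."""
    return pd.read_csv(io.StringIO(_SURVEY))


def survey_registry():
    """Expand the genus-level counts into (SampleRegistry, records).

    Within each genus the first ``n_colonized`` samples carry one
    Mucoromycotina detection; detected taxa cycle through the clade's pool of
    delimited taxa so that each clade exhibits its published number of
    distinct epMT.  Species labels cycle through each genus's species count.
    """
    df = survey_counts()
    rows, raw = [], []
    clade_cursor = {c: 0 for c in _EPMT_PER_CLADE}
    sid_n = 0
    for g in df.itertuples(index=False):
        for k in range(g.n_samples):
            sid_n += 1
            sid = f"LW{sid_n:04d}"
            species = f"{g.genus} sp{k % g.n_species + 1}"
            rows.append(
                {
                    "sample_id": sid,
                    "plant_species": species,
                    "plant_genus": g.genus,
                    "plant_clade": g.clade,
                    "country": "various",
                    "subregion": "",
                }
            )
            if k < g.n_colonized:
                pool = _EPMT_PER_CLADE[g.clade]
                tx = clade_cursor[g.clade] % pool + 1
                clade_cursor[g.clade] += 1
                raw.append((sid, f"epMT_{g.clade[:1]}{tx}", "Mucoromycotina"))
    registry = SampleRegistry(pd.DataFrame(rows).set_index("sample_id"))
    records = [OccurrenceRecord(s, t, l) for s, t, l in raw]
    return registry, records


_GENUS_TREE_NEWICK = (
    "(Takakia:1,((Treubia:1,Haplomitrium:1):1,((Neohodgsonia:1,(Lunularia:1,"
    "((Marchantia:1,Preissia:1):1,(((Plagiochasma:1,(Reboulia:1,(Mannia:1,"
    "(Asterella:1,Cryptomitrium:1):1):1):1):1,(Athalamia:1,(Clevea:1,"
    "Sauteria:1):1):1):1,((Targionia:1,Cyathodium:1):1,((Corsinia:1,"
    "Oxymitra:1):1,(Conocephalum:1,(Monoclea:1,Dumortiera:1):1):1):1):1):1)"
    ":1):1):1,((Noteroclada:1,Pellia:1):1,((Calycularia:1,(Sewardiella:1,"
    "(Allisonia:1,Fossombronia:1):1):1):1,(Phyllothallia:1,(Moerckia:1,"
    "(Hymenophyton:1,(Jensenia:1,(Pallavicinia:1,(Podomitrium:1,"
    "Symphyogyna:1):1):1):1):1):1):1):1):1):1):1);"
)


def genus_tree(include_outgroup: bool = True) -> dendropy.Tree:
    """Genus-level liverwort tree (synthetic unit branch lengths).

    Rooted on the moss outgroup *Takakia*; the Petalophyllaceae tip is
    labelled *Sewardiella* (its placement follows the sister genus
    *Petalophyllum*, the only other member of the family).
    """
    tree = dendropy.Tree.get(data=_GENUS_TREE_NEWICK, schema="newick")
    tree.is_rooted = True
    if not include_outgroup:
        keep = [t for t in tree.taxon_namespace if t.label != "Takakia"]
        tree = tree.extract_tree_with_taxa(taxa=keep)
        tree.purge_taxon_namespace()
    return tree


def glomeromycotina_character(include_outgroup: bool = True) -> dict:
    """Presence/absence of Glomeromycotina symbionts per genus."""
    absent = {
        "Treubia", "Haplomitrium", "Cryptomitrium", "Sauteria", "Cyathodium",
        "Corsinia", "Oxymitra", "Phyllothallia",
    }
    return _character(absent, include_outgroup)


def mucoromycotina_character(include_outgroup: bool = True) -> dict:
    """Presence/absence of Mucoromycotina symbionts per genus."""
    present = {
        "Treubia", "Haplomitrium", "Neohodgsonia", "Lunularia", "Asterella",
        "Plagiochasma", "Targionia", "Monoclea", "Pellia", "Calycularia",
        "Sewardiella", "Allisonia", "Fossombronia", "Moerckia", "Pallavicinia",
        "Symphyogyna",
    }
    tree = genus_tree(include_outgroup)
    return {
        t.label: (1 if t.label in present else 0) for t in tree.taxon_namespace
    }


def _character(absent, include_outgroup):
    tree = genus_tree(include_outgroup)
    out = {}
    for t in tree.taxon_namespace:
        if t.label == "Takakia":
            out[t.label] = 0  # the moss outgroup hosts neither lineage
        else:
            out[t.label] = 0 if t.label in absent else 1
    return out
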