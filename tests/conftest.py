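import numpy as np
import pandas as pd
import pytest

from mycosym.records import OccurrenceRecord, SampleRegistry


@pytest.fixture
def tiny_registry():
    df = pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "a3", "b1"],
            "plant_species": [
                "Treubia lacunosa",
                "Treubia lacunosa",
                "Fossombronia pusilla",
                "Marchantia sp.",
            ],
            "plant_genus": ["Treubia", "Treubia", "Fossombronia", "Marchantia"],
            "plant_clade": [
                "Haplomitriopsida",
                "Haplomitriopsida",
                "Pelliidae",
                "Marchantiopsida",
            ],
            "country": ["NZ", "NZ", "UK", "Chile"],
            "subregion": ["South Island", "South Island", "", ""],
        }
    ).set_index("sample_id")
    return SampleRegistry(df)


@pytest.fixture
def tiny_records():
    return [
        OccurrenceRecord("a1", "epMT1", "Mucoromycotina"),
        OccurrenceRecord("a2", "epMT1", "Mucoromycotina"),
        OccurrenceRecord("a3", "epMT2", "Mucoromycotina"),
        OccurrenceRecord("a3", "epGT1", "Glomeromycotina"),
        OccurrenceRecord("b1", "sing7", "Mucoromycotina", is_singleton=True),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_binary_matrix(rng, nr, nc, p):
    """Random matrix without empty rows/columns."""
    while True:
        M = (rng.random((nr, nc)) < p).astype(int)
        if M.sum(axis=1).all() and M.sum(axis=0).all():
            return M
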