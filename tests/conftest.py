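import numpy as np
import pandas as pd
import pytest

from amfgen.io_formats import METADATA_COLUMNS, OtuTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_metadata(samples, **overrides):
    """Minimal valid metadata: one row per (sample_id, plant_species,
    mesocosm_id) triple, other columns defaulted."""
    rows = []
    for sample_id, species, mesocosm in samples:
        row = {
            "sample_id": sample_id,
            "plant_species": species,
            "provenance": "native",
            "mesocosm_id": mesocosm,
            "community_id": mesocosm.split("M")[0],
            "prop_exotic_planted": 0.0,
            "herbivore": "excluded",
            "soil": "home",
            "soil_amn": 40.0,
            "richness_at_harvest": 8,
            "mycorrhizal_host": True,
        }
        row.update(overrides)
        rows.append(row)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 3], [2, 4, 0], [0, 0, 7]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["otu1", "otu2", "otu3"],
    )
    return OtuTable(counts)


@pytest.fixture
def small_metadata():
    return make_metadata(
        [("s1", "spA", "C01M1"), ("s2", "spB", "C01M1"), ("s3", "spA", "C02M1")]
    )
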