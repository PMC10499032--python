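import pandas as pd
import pytest
from hypothesis import settings

from matrisomekit import load_reference
from matrisomekit.tabular_io import OmicsTable

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

SPECIES_TAGS = {
    "human": "test-human",
    "mouse": "test-mouse",
    "zebrafish": "test-zebrafish",
    "fruit_fly": "test-fly",
    "nematode": "test-worm",
}


@pytest.fixture(scope="session")
def human_ref():
    return load_reference("test-human")


@pytest.fixture(scope="session")
def all_refs():
    return {species: load_reference(tag) for species, tag in SPECIES_TAGS.items()}


def make_table(columns: dict[str, list[str]]) -> OmicsTable:
    """Build an OmicsTable from literal text columns (test helper)."""
    return OmicsTable(df=pd.DataFrame({k: [str(v) for v in vals]
                                       for k, vals in columns.items()}, dtype=object))


@pytest.fixture
def small_table():
    return make_table({
        "ID": ["COL1A1", "ZZZ999", "P02452-2;JUNK1", "tgfb1"],
        "Count": ["3", "2", "5", "1"],
    })
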