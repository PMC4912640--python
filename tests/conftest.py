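import pandas as pd
import pytest

from spongenet.io_prep import CountTable, SampleMetadata


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The small synthetic study every I/O-level test reads from."""
    from spongenet.pipeline import make_fixtures

    return make_fixtures(tmp_path_factory.mktemp("study"), seed=0)


@pytest.fixture
def toy_table():
    """Three species x two replicates plus seawater; hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "OtuA": [50, 40, 0, 0, 30, 25, 1000],
            "OtuB": [5, 0, 60, 55, 0, 0, 0],
            "OtuC": [1, 2, 3, 4, 5, 6, 7],
            "OtuD": [0, 0, 0, 0, 0, 0, 500],
        },
        index=pd.Index(
            ["sp1_r1", "sp1_r2", "sp2_r1", "sp2_r2", "sp3_r1", "sp3_r2", "sw1"],
            name="sample_id",
        ),
    )
    return CountTable(counts)


@pytest.fixture
def toy_meta():
    rows = {
        "sp1_r1": ("speciesA", "sponge"),
        "sp1_r2": ("speciesA", "sponge"),
        "sp2_r1": ("speciesB", "sponge"),
        "sp2_r2": ("speciesB", "sponge"),
        "sp3_r1": ("speciesC", "sponge"),
        "sp3_r2": ("speciesC", "sponge"),
        "sw1": ("none", "seawater"),
    }
    df = pd.DataFrame(
        [(k, v[0], v[1]) for k, v in rows.items()],
        columns=["sample_id", "host_species", "habitat"],
    ).set_index("sample_id")
    return SampleMetadata(df)
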