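import numpy as np
import pandas as pd
import pytest

from commvade.phylo import parse_newick
from commvade.synthetic_community import SimConfig, simulate_study
from commvade.tables_io import AsvCountTable, SampleMetadata

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


def make_table(data: dict[str, dict[str, int]], asv_ids: list[str] | None = None):
    """Build an AsvCountTable from {sample: {asv: count}}."""
    if asv_ids is None:
        asv_ids = sorted({a for row in data.values() for a in row})
    counts = np.array(
        [[row.get(a, 0) for a in asv_ids] for row in data.values()], dtype=np.int64
    )
    return AsvCountTable(list(data), asv_ids, counts)


def make_metadata(rows: list[tuple[str, str, int]], week: int = 8):
    return SampleMetadata(
        pd.DataFrame(
            [
                {"sample_id": s, "treatment": t, "replicate": r, "week": week}
                for s, t, r in rows
            ]
        )
    )


@pytest.fixture
def toy_tree():
    return parse_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def default_study():
    """One default-config synthetic study shared across read-only tests."""
    return simulate_study(SimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
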