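import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixnet.core_data import ClusterRecord, SpeciesCatalog

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog() -> SpeciesCatalog:
    return SpeciesCatalog.default()


def make_records(cluster_species, sizes=None, habitat="grassland",
                 ecosystem="TME", season="wet"):
    """Build ClusterRecords from lists of species ids (group size 1 default)."""
    records = []
    for c, members in enumerate(cluster_species):
        sz = sizes[c] if sizes is not None else [1] * len(members)
        records.append(
            ClusterRecord(
                cluster_id=f"c{c + 1}",
                ecosystem=ecosystem,
                season=season,
                habitat=habitat,
                members=list(zip(members, sz)),
            )
        )
    return records


@pytest.fixture
def abc_records():
    """Clusters {A,B}, {A,B}, {A,C}, {B} on species ids from the catalog."""
    return make_records([["Wb", "Ze"], ["Wb", "Ze"], ["Wb", "GG"], ["Ze"]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
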