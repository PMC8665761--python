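import pytest
from hypothesis import HealthCheck, settings

import founderpan as fp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    return fp.table1_fixture()


@pytest.fixture(scope="session")
def table1_graph(table1):
    return fp.build_variant_graph(table1.reference, table1.records)


@pytest.fixture(scope="session")
def table1_paths(table1, table1_graph):
    return fp.haplotype_paths(table1_graph, table1.records, table1.samples)


@pytest.fixture(scope="session")
def table1_founders(table1, table1_graph):
    """L=4, f=4 founder reconstruction of the worked example."""
    return fp.reconstruct_founders(
        table1_graph, table1.records, table1.samples, L=4, f=4
    )
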