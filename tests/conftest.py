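import pytest

from plastidpoly import quadripartite as quad
from plastidpoly import synth

PANEL_SEED = 7


@pytest.fixture(scope="session")
def base_and_manifest():
    spec = synth.default_spec()
    return synth.make_base_plastome(spec, seed=PANEL_SEED)


@pytest.fixture(scope="session")
def base_record(base_and_manifest):
    return base_and_manifest[0]


@pytest.fixture(scope="session")
def base_partition(base_record):
    return quad.partition(base_record, min_ir_len=1000)


@pytest.fixture(scope="session")
def panel():
    """Two designed maternal groups of three accessions each."""
    return synth.two_group_panel(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def panel_records(panel):
    return panel[0]


@pytest.fixture(scope="session")
def panel_manifest(panel):
    return panel[1]


@pytest.fixture(scope="session")
def panel_partitions(panel_records):
    return [quad.partition(r, 1000) for r in panel_records]
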