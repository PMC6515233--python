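import numpy as np
import pytest

from papmine import motif_scan, seqio, synthetic_data


@pytest.fixture(scope="session")
def reference_rows():
    return seqio.load_reference_block_table()


@pytest.fixture(scope="session")
def patterns():
    return motif_scan.default_patterns()


@pytest.fixture(scope="session")
def reference_proteome():
    """Planted proteome built from the curated block table plus 10 decoys."""
    spec = synthetic_data.spec_from_reference_table(n_decoys=10, seed=11)
    records, truth = synthetic_data.generate_proteome(spec)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
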