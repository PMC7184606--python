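import pytest

from polyatails import simulate as sim


@pytest.fixture(scope="session")
def default_dataset():
    """Default three-class tail dataset (records, samples, truth), seed 0."""
    return sim.simulate_tail_dataset(sim.default_config(seed=0))


@pytest.fixture(scope="session")
def barcode_table():
    return sim.default_barcode_table()


@pytest.fixture(scope="session")
def spikein_small(barcode_table):
    """Small spike-in set: 40 reads/barcode, default noise and error rate."""
    return sim.simulate_spikein_reads(barcode_table, 40, seed=0)
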