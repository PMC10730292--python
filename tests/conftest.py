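import pytest

from mitoskew import SyntheticSpec, load_template, simulate_genome


@pytest.fixture(scope="session")
def template():
    return load_template()


@pytest.fixture(scope="session")
def standard_pair():
    """A default-condition synthetic genome and its ground truth."""
    return simulate_genome(SyntheticSpec(seed=11))


@pytest.fixture
def standard_genome(standard_pair):
    genome, _ = standard_pair
    return genome


def features_tuple(genome):
    return [
        (f.label, f.ftype, f.start, f.end, f.strand, f.codon_start,
         f.wraps_origin, f.copy_index)
        for f in genome.sorted_features()
    ]
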