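import numpy as np
import pytest

from its2otu.seqio import CountTable, UniqueSequence
from its2otu.simulate import ReadModel, make_clade_genomes, make_mapping, simulate_sample


@pytest.fixture(scope="session")
def two_clade_genomes():
    """Two genomes in different clades, dominants > 0.15 apart."""
    return make_clade_genomes(2, seed=101)


@pytest.fixture(scope="session")
def three_clade_genomes():
    return make_clade_genomes(3, seed=202)


@pytest.fixture(scope="session")
def small_isoclonal_sample(two_clade_genomes):
    """One isoclonal culture, 2000 reads, modest error rates."""
    g = two_clade_genomes[0]
    mapping = make_mapping(["iso"], seed=5)
    rm = ReadModel(barcode=mapping.rows[0].barcode)
    sim = simulate_sample([g], [1.0], 2000, rm, seed=6, sample_id="iso")
    return sim, mapping


def make_count_table(counts_by_seq, samples=("s1",)):
    """Helper: CountTable from {seq: count} or {seq: {sample: count}}."""
    variants = []
    for seq, c in counts_by_seq.items():
        if isinstance(c, dict):
            variants.append(UniqueSequence(seq, c))
        else:
            variants.append(UniqueSequence(seq, {samples[0]: c}))
    return CountTable(variants, list(samples))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
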