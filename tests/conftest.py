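import numpy as np
import pytest

from mitosignal import (
    CtGeneratorParams,
    SuitGeneratorParams,
    make_ct_dataset,
    make_genome_pair,
    make_suit_trace,
)


@pytest.fixture(scope="session")
def small_genomes():
    """6 kb mito + 20 kb nuclear contig carrying three planted NUMTs."""
    pair, truths = make_genome_pair(
        11,
        mito_length=6000,
        nuclear_length=20_000,
        numt_specs=[(500, 0.0), (400, 0.02), (300, 0.05)],
    )
    return pair, truths


@pytest.fixture(scope="session")
def clean_genomes():
    """Genome pair with no planted NUMTs."""
    pair, truths = make_genome_pair(12, mito_length=4000, nuclear_length=15_000, numt_specs=[])
    return pair, truths


@pytest.fixture()
def noise_free_ct():
    params = CtGeneratorParams(
        n_per_group=4,
        group_fold_changes={"RNR-6h": 2.07, "CCI-25h": {"pre": 0.84, "post": 1.35}},
        replicate_sd=0.0,
        animal_sd=0.0,
        seed=21,
    )
    table, truth = make_ct_dataset(params)
    return params, table, truth


@pytest.fixture(scope="session")
def default_suit_trace():
    params = SuitGeneratorParams(seed=31)
    trace, truth = make_suit_trace(params)
    return params, trace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
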