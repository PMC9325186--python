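import logging

import pytest

from phosphosig import SimConfig, simulate_dataset
from phosphosig.preprocessing import preprocess_matrix

logging.getLogger("phosphosig").setLevel(logging.ERROR)


def tiny_config(**overrides) -> SimConfig:
    """A fast, small study configuration for structural tests."""
    base = dict(
        n_proteins=400,
        n_phosphosites=400,
        frac_differential=0.03,
        n_genesets=10,
        geneset_size_range=(5, 15),
        n_planted_sets=2,
        n_kinases=8,
        substrates_per_kinase=6,
        n_active_kinases=2,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    """One small simulated study shared across structural tests."""
    return simulate_dataset(tiny_config())


@pytest.fixture(scope="session")
def tiny_normalized(tiny_dataset):
    """Discovery-cohort normalized proteome of the tiny study."""
    proteome, _, design, *_ = tiny_dataset
    disc = [d.sample_id for d in design if d.cohort == "discovery"]
    norm, report = preprocess_matrix(proteome.subset_samples(disc), design)
    return norm, report, design
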