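import numpy as np
import pytest

from spongelinc import SimConfig, simulate_counts, simulate_genome

BASES = np.array(list("ACGT"))


def random_seq(rng, length):
    return "".join(BASES[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic dataset (seed 42, default conditions)."""
    return simulate_genome(SimConfig())


@pytest.fixture(scope="session")
def default_counts(default_dataset):
    return simulate_counts(default_dataset)


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced dataset for fast pipeline-level tests."""
    return SimConfig(
        seed=7, n_scaffolds=6, scaffold_len=120_000, n_coding=40,
        n_linc=40, n_pseudo_decoys=10, n_overlap_decoys=10,
        n_short_decoys=10, n_modules=2, module_size=12,
        n_correlated_pairs=8,
    )
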