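import numpy as np
import pytest

from aluexon.pipeline import simulate_insertion_study
from aluexon.simulate import SimConfig, generate_locus_set


@pytest.fixture(scope="session")
def insertion_study():
    """One simulated non-reference-insertion experiment, analyzed once and
    shared: 20 genes, 5 planted insertions, 5 guaranteed signal pairs each."""
    return simulate_insertion_study(seed=1, n_genes=20, n_insertions=5)


@pytest.fixture(scope="session")
def fixed_locus_set():
    """A cohort-style locus set with planted fixed (reference) Alu exons."""
    return generate_locus_set(SimConfig(seed=3, n_genes=12, n_fixed_exonizations=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
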