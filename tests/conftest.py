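import numpy as np
import pytest

from thermoclades import synthdata as sd


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb, 3-contig genome with 8 planted CDS (session-cached)."""
    spec = sd.GenomeSpec(n_contigs=3, total_length=20_000, n_cds=8, seed=11)
    contigs, truth = sd.generate_genome(spec)
    return spec, contigs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
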