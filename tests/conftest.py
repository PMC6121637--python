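import logging

import numpy as np
import pytest

from methlink.simulate import SimConfig, generate_fixture

logging.getLogger("methlink").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_fixture():
    """Compact planted dataset shared by unit tests: one 400-kb
    chromosome, 40 genes, 20 planted DMRs."""
    cfg = SimConfig(
        genome_length=400_000,
        n_chromosomes=1,
        n_genes=40,
        n_tes=40,
        n_dmrs=20,
        seed=11,
    )
    return generate_fixture(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
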