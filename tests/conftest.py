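import numpy as np
import pytest

from nslseq.io import GenomeLayout
from nslseq.pipeline import RunConfig, run_synthetic_analysis
from nslseq.simulate import SynthConfig, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """Small synthetic genome shared across read-level tests."""
    cfg = SynthConfig(seed=7, n_genes=200, chrom_length=1_500_000)
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def default_run():
    """Full default pipeline run (1,000 genes, seed 1), shared by the
    recovery-style tests."""
    return run_synthetic_analysis(RunConfig(seed=1))


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
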