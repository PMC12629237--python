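import numpy as np
import pytest

from xdc.genome import make_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_chrom_genome():
    """One autosome + one X, 10 Mb each at 5 kb bins."""
    return make_genome(
        [("chr1", 10_000_000, "autosome"), ("chrX", 10_000_000, "X")],
        bin_size=5000,
    )


@pytest.fixture
def four_chrom_genome():
    """Three autosomes + X, 3 Mb each at 10 kb bins: cheap expression/ChIP
    simulations."""
    return make_genome(
        [
            ("I", 3_000_000, "autosome"),
            ("II", 3_000_000, "autosome"),
            ("III", 3_000_000, "autosome"),
            ("X", 3_000_000, "X"),
        ],
        bin_size=10_000,
    )
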