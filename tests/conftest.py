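import numpy as np
import pytest

from hmdkit.intervals import GenomeInterval
from hmdkit.synthetic import SyntheticGenomeSpec, generate


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomeInterval(str(rng.choice(chroms)), start, start + length,
                                  name=f"iv{i}"))
    return out


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic genome shared by read-only tests."""
    return generate(SyntheticGenomeSpec(seed=7))


@pytest.fixture
def small_spec():
    """A small, fast genome for tests that regenerate repeatedly."""
    return SyntheticGenomeSpec(
        seed=3,
        n_chroms=1,
        chrom_len_bp=300_000,
        n_promoters=6,
        n_enhancers=8,
        n_unannotated_promoters=2,
        n_promoter_candidates=2,
    )
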