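import numpy as np
import pytest

from endosign import SimulationConfig
from endosign.chip_signal import BinTrack, CoverageTrack


@pytest.fixture
def small_config():
    """A quick-to-simulate configuration with the default class structure."""
    return SimulationConfig(n_genes=60, chrom_length=500_000, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_bintrack(values, bin_width=10, chrom="Chr1", **kwargs):
    return BinTrack(bin_width=bin_width, values={chrom: np.asarray(values, dtype=float)}, **kwargs)


def make_coverage(values, step=1, chrom="Chr1"):
    return CoverageTrack(step=step, values={chrom: np.asarray(values, dtype=float)})
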