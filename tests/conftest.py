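import numpy as np
import pytest

from xikit.core import SnpTable
from xikit.simulate import SimulationConfig, default_config


@pytest.fixture
def small_config() -> SimulationConfig:
    """A 2 Mb chromosome with the default planted layout."""
    return default_config(seed=11, chrom_length=2_000_000)


@pytest.fixture
def tiny_snps() -> SnpTable:
    """Hand-written SNP table for exact assignment checks."""
    return SnpTable("chrX",
                    positions=np.array([100, 250, 400, 900]),
                    allele_hap1=np.array(["A", "C", "G", "T"]),
                    allele_hap2=np.array(["G", "T", "A", "C"]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
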