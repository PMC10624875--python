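"""Shared fixtures: in-memory synthetic studies at two scales.

``small_study`` is a fast fixture for plumbing and invariant tests;
``power_study`` is a moderate one (two 250 kb chromosomes, 100 injected DMCs
per cryoprotectant) used for recovery and distributional checks.
"""

import numpy as np
import pytest

from cryomethyl.simulate import SimulationConfig, simulate_study
from cryomethyl.types import CytosineRecord, SampleMethylome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_chrom=2, chrom_length=60_000,
                            n_dmc_true=20, n_genes=10)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def power_config():
    return SimulationConfig(seed=7, n_chrom=2, chrom_length=250_000, n_dmc_true=100)


@pytest.fixture(scope="session")
def power_study(power_config):
    return simulate_study(power_config)


def make_sample(ratio_depth_pairs, male_id=1, condition="fresh", chrom="chr1",
                start=100, step=10, strand="+"):
    """Build a SampleMethylome from (ratio, depth) pairs at spaced positions."""
    s = SampleMethylome(male_id=male_id, condition=condition)
    for i, (ratio, depth) in enumerate(ratio_depth_pairs):
        k = int(round(ratio * depth))
        s.add(CytosineRecord(chrom, start + i * step, strand, k, depth - k))
    return s


@pytest.fixture
def sample_factory():
    return make_sample
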