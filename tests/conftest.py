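import numpy as np
import pytest

from sdweaver import (Sequence, TopologySpec, build_collapsed_contig,
                      build_index, evolve_units, sample_reads)
from sdweaver.simulator import random_bases


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def flat2_truth():
    """Two SD copies at 99.5% identity to the root on a collapsed contig
    with unique flanks and a unique spacer before the second unit."""
    root = Sequence("root", random_bases(np.random.default_rng(101), 8000))
    truth = evolve_units(root, TopologySpec("flat", 2), 0.005, seed=102)
    return build_collapsed_contig(truth, flank_len=4000, seed=103, spacer_len=2000)


@pytest.fixture(scope="session")
def flat2_reads(flat2_truth):
    return sample_reads(flat2_truth.collapsed_contig, coverage=40,
                        mean_len=5000, sd_len=1000, error_rate=0.15, seed=104,
                        unit_intervals=flat2_truth.unit_intervals)


@pytest.fixture(scope="session")
def flat2_errorfree_reads(flat2_truth):
    return sample_reads(flat2_truth.collapsed_contig, coverage=20,
                        mean_len=5000, sd_len=1000, error_rate=0.0, seed=105,
                        rc_prob=0.0, unit_intervals=flat2_truth.unit_intervals)


@pytest.fixture(scope="session")
def flat2_index(flat2_reads):
    return build_index([r.seq for r in flat2_reads])
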