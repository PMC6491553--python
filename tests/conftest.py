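import numpy as np
import pytest

from berrymir.config import SimulationConfig
from berrymir.synthetic_data import simulate_dataset

# mixed defect schedule: 14 loci within the acceptance thresholds
# (mispairings <= 4, bulges <= 1), 6 beyond them
GOOD_SCHEDULE = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0), (0, 1), (1, 1),
                 (2, 1), (3, 1), (4, 1), (0, 0), (2, 0), (4, 0), (2, 1)]
BAD_SCHEDULE = [(5, 0), (6, 0), (7, 0), (5, 1), (6, 1), (5, 0)]
MIXED_MISPAIRINGS = [m for m, _ in GOOD_SCHEDULE + BAD_SCHEDULE]
MIXED_BULGES = [b for _, b in GOOD_SCHEDULE + BAD_SCHEDULE]


def mixed_dataset(seed: int, **overrides):
    cfg = SimulationConfig(seed=seed, **overrides)
    return simulate_dataset(cfg, MIXED_MISPAIRINGS, MIXED_BULGES)


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic dataset shared across the session."""
    return mixed_dataset(seed=101)


@pytest.fixture(scope="session")
def small_dataset():
    """Cheaper dataset for stages that do not need the full pipeline."""
    cfg = SimulationConfig(seed=7, n_true_mirnas=6, read_depth=2000,
                           n_genes=20)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def phred_reads(ds):
    """Dataset FASTQ records as (id, seq, quality-score-list) tuples."""
    return [(r.id, r.seq, [ord(c) - 33 for c in r.qual]) for r in ds.reads]
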