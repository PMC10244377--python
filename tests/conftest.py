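import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from clipsplice.simulate import SimConfig, generate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic cohort at the default study conditions."""
    return generate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced cohort for fast structural tests."""
    return generate_all(
        SimConfig(
            seed=7,
            n_genes=30,
            n_mirs=40,
            n_replicates=2,
            afm_grid=(8, 8),
            n_lsv_events=12,
        )
    )
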