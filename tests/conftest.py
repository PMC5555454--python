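import numpy as np
import pandas as pd
import pytest

from germscan.gio import GenotypeMatrix
from germscan.syndata import SimulationConfig, simulate

NA = np.nan


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """Five accessions x four markers with known per-marker statistics."""
    dosage = np.array(
        [
            [0, 2, 1, NA],
            [0, 2, 0, 2],
            [2, NA, 0, 2],
            [2, 2, 2, NA],
            [1, 2, 2, 2],
        ],
        dtype=float,
    )
    return GenotypeMatrix([f"acc{i}" for i in range(1, 6)], [f"m{j}" for j in range(1, 5)], dosage)


@pytest.fixture(scope="session")
def sim_small():
    """Cheap three-group panel reused by read-only tests."""
    return simulate(SimulationConfig(seed=11, n_per_group=30, markers_per_lg=40,
                                     n_linkage_groups=3))


@pytest.fixture(scope="session")
def sim_default():
    """Default-scale panel (3 x 100 accessions, ~2,000 loci), shared read-only."""
    return simulate(SimulationConfig(seed=5))
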