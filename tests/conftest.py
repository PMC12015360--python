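import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from geoqual.synthetic_data import SimulationConfig, simulate_survey

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir():
    return DATA


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey reused by read-only tests."""
    cfg = SimulationConfig(seed=11, n_clusters=60, grid_shape=(15, 15),
                           n_districts=5, mean_cluster_size=30.0)
    return simulate_survey(cfg)


@pytest.fixture(scope="session")
def medium_counts():
    """Cluster counts at a size where the spatial signal is identifiable."""
    cfg = SimulationConfig(seed=21, n_clusters=150, grid_shape=(20, 20),
                           n_districts=6, mean_cluster_size=30.0)
    sv = simulate_survey(cfg)
    return sv
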