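import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

DATA_DIR = Path(__file__).parent / "data"


def make_lines(pops, pf, y, mass=None, species="sp"):
    """Line-summary frame from parallel lists (one entry per line)."""
    n = len(pf)
    if mass is None:
        mass = [5.0] * n
    return pd.DataFrame(
        {
            "species_id": species,
            "population_id": list(pops),
            "maternal_line_id": [f"L{i}" for i in range(n)],
            "n_planted": 20,
            "n_emerged": 10,
            "n_persistent": 5,
            "n_dead": 5,
            "mean_sqrt_emergence": list(y),
            "mean_seed_mass": list(mass),
            "viable_fraction": 0.75,
            "persistence_fraction": list(pf),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def data_dir():
    return DATA_DIR
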