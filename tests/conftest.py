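import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles / study_values

from econetkit import synthetic
from econetkit.grid import Grid


@pytest.fixture(scope="session")
def demo_spec():
    """Small but structured landscape used across module tests."""
    return synthetic.SynthSpec(
        shape=(96, 128), cell_size=90.0, autocorrelation_range=4.0,
        urban_radius_cells=10, seed=42,
    )


@pytest.fixture(scope="session")
def demo_dem(demo_spec):
    return synthetic.make_dem(demo_spec)


@pytest.fixture(scope="session")
def demo_landcover(demo_spec, demo_dem):
    return synthetic.make_landcover(demo_spec, demo_dem)


def random_binary_grid(rng, shape, p=0.55):
    """Random foreground/background landscape as a Grid."""
    return Grid((rng.random(shape) < p).astype(np.int8), cell_size=30.0)
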