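import numpy as np
import pytest

from cervidyn.io import TaxaCountTable
from cervidyn.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_table():
    return TaxaCountTable(
        sample_ids=("s1", "s2", "s3"),
        taxon_names=(
            "Lactobacillus crispatus",
            "Lactobacillus iners",
            "Gardnerella vaginalis",
            "Prevotella bivia",
        ),
        counts=np.array(
            [
                [60, 20, 15, 5],
                [5, 55, 30, 10],
                [0, 10, 50, 40],
            ]
        ),
    )


@pytest.fixture
def small_config():
    return SimulationConfig(seed=11, n_subjects=25, depth_mean=2000.0)
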