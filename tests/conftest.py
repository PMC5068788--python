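import numpy as np
import pytest

from ocplsda import SimulationDesign, simulate_dataset
from ocplsda.datagen import CASE_CLASS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """24 samples, 120 features, strong markers, mild confounding."""
    design = SimulationDesign(n_per_group=12, n_features=120, n_markers=12,
                              n_confounded=12, marker_effect=2.0,
                              confounder_class_assoc=0.4, seed=7)
    return simulate_dataset(design)


@pytest.fixture(scope="session")
def case_label():
    return CASE_CLASS
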