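import numpy as np
import pandas as pd
import pytest

from toximpute import SyntheticConfig, generate_panel
from toximpute.learners import LearnerSpec
from toximpute.splitting import assay_split


@pytest.fixture(scope="session")
def fast_spec():
    """A small, quick gradient-boosting spec used throughout the suite."""
    return LearnerSpec.make("boosting", n_estimators=40, max_depth=4)


@pytest.fixture(scope="session")
def small_panel():
    """800-compound, 6-assay panel with overlapping mechanism loadings."""
    cfg = SyntheticConfig(n_compounds=800, n_assays=6, n_bits=256, seed=7)
    features, labels, truth = generate_panel(cfg)
    return cfg, features, labels, truth


@pytest.fixture(scope="session")
def small_split(small_panel):
    _, _, labels, _ = small_panel
    return assay_split(labels, test_fraction=0.2, seed=0)


@pytest.fixture
def toy_labels():
    """Tiny hand-written sparse label matrix."""
    return pd.DataFrame(
        [[1, 0, np.nan],
         [1, np.nan, 0],
         [0, 1, 1],
         [np.nan, 1, 0],
         [1, 0, 1],
         [0, 0, np.nan]],
        index=[f"c{i}" for i in range(6)],
        columns=["A", "B", "C"], dtype=float)
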