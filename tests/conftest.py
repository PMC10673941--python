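import numpy as np
import pytest

from nucleogate.presets import untreated_baseline
from nucleogate.workflows import analyze_config, balanced_feature_cohort


@pytest.fixture(scope="session")
def untreated_small():
    """Analyzed untreated scene: 10 spheroids x 40 nuclei + 20 fibroblasts."""
    arms = untreated_baseline(11, n_spheroids=10, nuclei_per_spheroid=40,
                              n_fibroblasts=20)
    return analyze_config(arms["untreated"], with_features=True,
                          with_celltypes=True)


@pytest.fixture(scope="session")
def cohort400():
    """Measured features for 400 nuclei in 4 exactly balanced classes."""
    features, labels, matched = balanced_feature_cohort(1, n_per_class=100)
    return features, labels, matched


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
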