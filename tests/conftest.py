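import numpy as np
import pytest

from corneaselect import FeatureTable, PlantedDesign, generate_planted_features


@pytest.fixture(scope="session")
def planted_small():
    """6-channel / 2-informative planted table with a strong effect."""
    design = PlantedDesign(
        n_samples=160, n_channels=6, k_informative=2, effect_size=5.0, seed=7
    )
    values, labels, informative = generate_planted_features(design)
    return FeatureTable(values, labels), informative


@pytest.fixture(scope="session")
def planted_medium():
    """64-channel / 8-informative table for selection experiments."""
    design = PlantedDesign(
        n_samples=300, n_channels=64, k_informative=8, effect_size=5.0, seed=11
    )
    values, labels, informative = generate_planted_features(design)
    return FeatureTable(values, labels), informative


@pytest.fixture
def rng():
    return np.random.default_rng(0)
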