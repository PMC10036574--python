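import numpy as np
import pytest

from qsarscreen import (
    SyntheticSpec,
    fit_ad,
    generate_dataset,
    train_ensemble,
)


@pytest.fixture(scope="session")
def dataset():
    """Reference synthetic dataset: 400 balanced compounds, 54 descriptors."""
    return generate_dataset(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def strong_dataset():
    """Well-separated dataset (effect size 3) for separability checks."""
    return generate_dataset(SyntheticSpec(effect_size=3.0, seed=11))


@pytest.fixture(scope="session")
def ensemble(dataset):
    """Four-model ensemble trained on the full reference dataset."""
    return train_ensemble(dataset.descriptors, dataset.labels)


@pytest.fixture(scope="session")
def ad_model(dataset):
    return fit_ad(dataset.descriptors)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
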