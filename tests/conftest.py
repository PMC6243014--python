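import numpy as np
import pytest

from herbprint.featurize import build_dataset, featurize_peak_table
from herbprint.simulate import default_fixture


@pytest.fixture(scope="session")
def fixture_peaks():
    """Default synthetic condition: 10 species x 30 replicates, 10% dropout,
    plus 3 rare species x 5 replicates for the negative-class rule."""
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_dataset(fixture_peaks):
    return build_dataset(featurize_peak_table(fixture_peaks))


@pytest.fixture(scope="session")
def main_dataset():
    """10 species x 30 replicates only (no rare species)."""
    peaks = default_fixture(seed=0, rare_species=0)
    return build_dataset(featurize_peak_table(peaks))


@pytest.fixture(scope="session")
def holdout_split(main_dataset):
    from sklearn.model_selection import train_test_split

    y = main_dataset.labels()
    tr, te = train_test_split(
        np.arange(y.size), test_size=0.2, stratify=y, random_state=0
    )
    return tr, te
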