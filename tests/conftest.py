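import numpy as np
import pytest

from vitseq.fixtures import SyntheticFeatureSpec, make_feature_dataset


def dataset_arrays(sequences):
    """Stack a list of FeatureSequence into (X, y) arrays."""
    X = np.stack([s.features for s in sequences])
    y = np.array([s.label_code for s in sequences], dtype=np.int64)
    return X, y


@pytest.fixture(scope="session")
def small_separable():
    """Well-separated small dataset: 3 classes x 15 subjects, 10 x 8 sequences."""
    spec = SyntheticFeatureSpec(
        n_per_class=15, seq_len=10, feature_dim=8,
        separation=6.0, positional_signal=1.0, seed=11,
    )
    return make_feature_dataset(spec)


@pytest.fixture(scope="session")
def small_separable_arrays(small_separable):
    return dataset_arrays(small_separable)
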