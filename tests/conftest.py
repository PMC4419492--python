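import numpy as np
import pytest

import rusmote as rm


@pytest.fixture
def separated_dataset() -> rm.LabeledDataset:
    """75/454 two-cluster dataset, clusters 10 SD apart: no boundary noise."""
    spec = rm.GeneratorSpec(n_min=75, n_maj=454, separation=10.0, seed=11)
    return rm.make_gaussian_imbalanced(spec)


@pytest.fixture(scope="session")
def cohort_features() -> rm.LabeledDataset:
    """Feature table of the study-scale cohort (150 nodules / 908 tubes)."""
    volumes, labels = rm.make_paperlike_cohort(seed=42)
    X = rm.features_to_array([rm.feature_vector(v) for v in volumes])
    ids = tuple(v.id for v in volumes)
    return rm.LabeledDataset(X, labels, sample_ids=ids)
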