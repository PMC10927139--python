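from importlib import resources

import numpy as np
import pytest

from iggpso import (
    EvalProtocol,
    ExpressionDataset,
    SyntheticSpec,
    generate,
    read_score_table,
)


def _packaged_table(name):
    with resources.as_file(resources.files("iggpso").joinpath(f"data/{name}")) as p:
        return read_score_table(p)


@pytest.fixture(scope="session")
def svm_table():
    """Published SVM ACC+FS comparison scores: 8 rows x 13 algorithms."""
    return _packaged_table("svm_scores.csv")


@pytest.fixture(scope="session")
def knn_table():
    """Published KNN ACC+FS comparison scores: 8 rows x 13 algorithms."""
    return _packaged_table("knn_scores.csv")


@pytest.fixture
def tiny_dataset():
    """4 samples x 2 features, binary classes, hand-checkable."""
    return ExpressionDataset(
        expression=np.array([[0.0, 5.0], [0.1, 3.0], [1.0, 4.0], [1.1, 6.0]]),
        labels=np.array(["a", "a", "b", "b"]),
        feature_ids=["f0", "f1"],
        sample_ids=["s0", "s1", "s2", "s3"],
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Small planted-structure dataset with clearly separable classes."""
    spec = SyntheticSpec(
        n_samples=60,
        n_features=150,
        n_informative=10,
        n_redundant=10,
        n_classes=2,
        effect_size=2.0,
        seed=42,
    )
    dataset, roles = generate(spec)
    return dataset, roles


@pytest.fixture(scope="session")
def fast_protocol():
    return EvalProtocol(cv_folds=3, cv_seed=0)
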