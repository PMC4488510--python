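import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cm1subtype.cm1 import balanced_top_k, cm1_rank_all
from cm1subtype.ensemble import cross_validate_consensus
from cm1subtype.simulate import GeneratorConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# scikit-learn convergence chatter from the weaker ensemble members is
# expected at desk-scale sample sizes and irrelevant to the assertions
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture(scope="session")
def strong_dataset():
    """Well-separated five-subtype dataset (effect/noise = 4)."""
    config = GeneratorConfig(seed=7)
    matrix, labels, manifest = generate_dataset(config)
    return config, matrix, labels, manifest


@pytest.fixture(scope="session")
def strong_selection(strong_dataset):
    _, matrix, labels, _ = strong_dataset
    table = cm1_rank_all(matrix, labels)
    return table, balanced_top_k(table)


@pytest.fixture(scope="session")
def strong_consensus(strong_dataset, strong_selection):
    """Cross-validated ensemble consensus on the well-separated dataset.

    Session-scoped: the 24-model x 10-fold run is the suite's one
    expensive computation and several tests read it.
    """
    _, matrix, labels, _ = strong_dataset
    _, selection = strong_selection
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        predictions, consensus = cross_validate_consensus(
            matrix, labels, selection, folds=10, seed=7
        )
    return predictions, consensus


@pytest.fixture
def toy_labels():
    """Two small labellings of the same ten samples."""
    idx = pd.Index([f"s{i}" for i in range(10)], name="sample_id")
    a = pd.Series(["LA"] * 5 + ["B"] * 5, index=idx)
    b = pd.Series(["LA"] * 4 + ["B"] * 6, index=idx)
    return a, b
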