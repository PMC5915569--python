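import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rnam5c as r

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_small():
    """A small strong-signal simulation shared across tests."""
    cfg = r.SimConfig(
        n_transcripts=20,
        length_range=(300, 600),
        n_positives=40,
        epsilon=1.0,
        seed=11,
    )
    transcripts, truth = r.simulate_dataset(cfg)
    return cfg, transcripts, truth


@pytest.fixture(scope="session")
def dataset_small(sim_small):
    """Labeled 11-nt windows (40 positives, ~400 negatives)."""
    _, transcripts, truth = sim_small
    windows, labels = r.labeled_windows_from_simulation(
        transcripts, truth, neg_per_pos=10, upstream=5, downstream=5, seed=5
    )
    X = r.encode_windows(windows)
    names = r.feature_names(11)
    return windows, X, labels, names


@pytest.fixture(scope="session")
def cv_small(dataset_small):
    _, X, labels, names = dataset_small
    auc, pooled, pooled_labels, fold_aucs = r.cross_validate(
        X, labels, seed=2, folds=5
    )
    return auc, pooled, pooled_labels, fold_aucs


@pytest.fixture(scope="session")
def trained_model(dataset_small, cv_small):
    _, X, labels, names = dataset_small
    _, pooled, pooled_labels, _ = cv_small
    model = r.train_ensemble(
        X[labels == 1], X[labels == 0], seed=3,
        feature_names=names, upstream=5, downstream=5,
    )
    model.thresholds = r.determine_thresholds(pooled, pooled_labels)
    return model
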