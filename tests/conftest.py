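import numpy as np
import pytest

from vpgap.predictivity import CVConfig
from vpgap.synthetic import (
    TruthConfig,
    generate_hierarchy,
    generate_sessions,
    generate_stimuli,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated experiment reused across tests.

    80 ID + 40 OOD stimuli, 3-layer ReLU hierarchy, 12 sites spread over
    the layers, moderate noise.
    """
    stimuli = generate_stimuli(80, 40, 8, seed=11)
    reference = generate_stimuli(100, 2, 8, seed=12).subset("ID")
    hierarchy = generate_hierarchy(8, [30, 30, 30], "relu", seed=13)
    sessions, truth = generate_sessions(
        hierarchy, stimuli, 12, TruthConfig(noise_sd=0.5), rep_range=(20, 20), seed=14
    )
    return {
        "stimuli": stimuli,
        "reference": reference,
        "hierarchy": hierarchy,
        "sessions": sessions,
        "truth": truth,
        "Y": {d: sessions[d].trial_mean() for d in ("ID", "OOD")},
        "site_ids": sessions["ID"].site_ids,
    }


@pytest.fixture
def quick_cv():
    return CVConfig(n_folds=5, n_components=10, n_repetitions=2, seed=21)


@pytest.fixture(scope="session")
def scored_world(small_world):
    """The small world scored across all layers with the default-style CV."""
    from vpgap.pipeline import score_model

    cv = CVConfig(n_folds=5, n_components=15, n_repetitions=2, seed=31)
    table = score_model(
        small_world["hierarchy"],
        small_world["stimuli"],
        small_world["reference"],
        small_world["Y"],
        small_world["site_ids"],
        cv,
    )
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
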