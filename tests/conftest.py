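import numpy as np
import pytest

import semdecode as sd


@pytest.fixture(scope="session")
def make_dataset():
    """Factory for small synthetic datasets, cached per parameter set."""
    cache = {}

    def _make(
        seed=7,
        gain=0.0,
        n_participants=3,
        artifact_rate=0.0,
        exposures_to_acquire=1,
        electrode_subset=None,
        n_electrodes=32,
        electrodes=None,
        vector_dim=50,
    ):
        key = (seed, gain, n_participants, artifact_rate, exposures_to_acquire,
               electrode_subset, n_electrodes, electrodes, vector_dim)
        if key not in cache:
            fwd = sd.ForwardModel(
                gain=gain,
                artifact_rate=artifact_rate,
                electrode_subset=electrode_subset,
            )
            learner = sd.LearnerModel(kind="perfect", exposures_to_acquire=exposures_to_acquire)
            cache[key] = sd.simulate_dataset(
                seed=seed,
                learner=learner,
                fwd=fwd,
                n_participants=n_participants,
                n_electrodes=n_electrodes,
                electrodes=electrodes,
                vector_dim=vector_dim,
            )
        return cache[key]

    return _make


def design_from(epochs, vectors, window=(0.0, 500.0), min_exposures=6, drop_first=2):
    """Run the standard preprocessing chain down to (X, Y)."""
    clean, _ = sd.reject_artifacts(sd.trim_epochs(epochs))
    sel = sd.select_trials(clean, min_exposures=min_exposures, drop_first=drop_first)
    tensor = sd.select_window(sd.average_selected(sel), sd.WindowSpec(*window))
    X = sd.flatten(tensor)
    return X.X, vectors.Y[tensor.symbols]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
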