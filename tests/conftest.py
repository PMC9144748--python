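import numpy as np
import pytest

import gaitcount as gc


def build_window_dataset(recordings, **window_kwargs):
    """Detected-label window dataset from a list of synthetic recordings."""
    parts = []
    for i, rec in enumerate(recordings):
        mag = gc.preprocess_accel(rec.accel)
        events = gc.detect_steps(gc.preprocess_pressure(rec.pressure))
        parts.append(
            gc.make_windows(mag, events, rec.scenario.position, recording_id=i, **window_kwargs)
        )
    return gc.WindowDataset.concatenate(parts)


@pytest.fixture(scope="session")
def small_cohort():
    """Nine 2-minute recordings (3 positions x 3 cadences), fixed seeds."""
    return gc.generate_cohort(gc.default_cohort_scenarios(duration_s=120.0, base_seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_window_dataset(small_cohort)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """Ensemble fitted on the small cohort with a shortened MLP budget."""
    train, _ = gc.split_dataset(small_dataset)
    model = gc.EnsembleStepCounter(
        random_state=0, regressor_hyperparams={"mlp": {"max_iter": 150}}
    )
    return model.fit_dataset(train)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return gc.split_dataset(small_dataset)
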