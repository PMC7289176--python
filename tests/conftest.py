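import numpy as np
import pytest

from gaitvid import (
    FeatureConfig,
    GaitSimParams,
    NormalizationContext,
    filter_trajectory,
    simulate_bout,
    threshold_and_impute,
)
from gaitvid.features import detect_events


@pytest.fixture(scope="session")
def clean_bout_truth():
    """A noiseless, dropout-free symmetric bout with its ground truth."""
    params = GaitSimParams(seed=7, pixel_noise_sd=0.0, dropout_rate=0.0)
    return simulate_bout(params)


@pytest.fixture(scope="session")
def noisy_bout_truth():
    """A bout with detector-like noise, dropouts and perspective growth."""
    params = GaitSimParams(
        seed=11,
        pixel_noise_sd=1.5,
        dropout_rate=0.1,
        perspective_scale_end=1.8,
        stance_time_split=0.55,
    )
    return simulate_bout(params)


@pytest.fixture(scope="session")
def clean_pipeline(clean_bout_truth):
    """Filtered trajectory, normalization context and events for the clean bout."""
    bout, truth = clean_bout_truth
    traj = filter_trajectory(threshold_and_impute(bout))
    context = NormalizationContext.from_trajectory(traj)
    events = detect_events(traj, FeatureConfig())
    return bout, truth, traj, context, events
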