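import numpy as np
import pytest
from hypothesis import settings

from pockethar.synthetic_data import (
    AcquisitionParams,
    ActivitySignalParams,
    generate_recording,
)
from pockethar.types import Activity
from pockethar.windowing import SensorWindow, WindowingConfig, segment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def walking_recording():
    params = ActivitySignalParams.for_activity(Activity.WALKING)
    return generate_recording(params, AcquisitionParams(seed=42))


@pytest.fixture
def walking_window(walking_recording):
    (window,) = segment(walking_recording, WindowingConfig())
    return window


def random_window(rng: np.random.Generator, n: int = 100) -> SensorWindow:
    """A structureless random window for oracle tests."""
    return SensorWindow(data=rng.normal(0.0, 5.0, size=(3, 3, n)))
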