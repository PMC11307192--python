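import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from criticalhr import EffortTrial, HRSample, HRSeries, Session

settings.register_profile(
    "fixed", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def trial_factory():
    """Build an EffortTrial from a list of HR sample values."""

    def make(hr_values, time_s, distance_m=400.0, interval_s=5.0,
             participant_id="p1", session=Session.test):
        samples = [
            HRSample(elapsed_s=interval_s * (i + 1), hr_bpm=float(h))
            for i, h in enumerate(hr_values)
        ]
        series = HRSeries(samples=samples, sampling_interval_s=interval_s)
        return EffortTrial(
            participant_id=participant_id, session=session,
            distance_m=distance_m, time_s=time_s, series=series,
        )

    return make


@pytest.fixture
def constant_hr_trial(trial_factory):
    """Constant 120 b/min for 300 s sampled every 5 s."""
    return trial_factory([120.0] * 60, time_s=300.0)
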