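import numpy as np
import pytest

import physiofuse as pf
from physiofuse.synth import simulate_hr_trajectory, synth_ecg


@pytest.fixture(scope="session")
def exercise_timeline():
    return pf.make_timeline(pf.EXERCISE_TEMPLATE, start_ns=0)


@pytest.fixture(scope="session")
def occlusion_timeline():
    return pf.make_timeline(pf.OCCLUSION_TEMPLATE, start_ns=0)


@pytest.fixture(scope="session")
def exercise_hr(exercise_timeline):
    return simulate_hr_trajectory(exercise_timeline, hr_rest=60.0, hr_max=190.0, tau_s=30.0)


@pytest.fixture(scope="session")
def clean_exercise_ecg(exercise_hr):
    """One seeded low-noise exercise-ramp ECG with ground-truth beats."""
    stream, beat_times = synth_ecg(exercise_hr, 0.0, 720.0, fs=200.0, noise_sd=0.02, seed=11)
    return stream, beat_times


def random_stream(rng, rate_hz, duration_s, device="dev", metric="m", t0_s=0.0):
    """Helper: jittered-rate stream of random values for fusion tests."""
    n = max(int(duration_s * rate_hz), 1)
    t = t0_s + np.arange(n) / rate_hz + rng.uniform(0, 0.2 / rate_hz, n)
    t = np.sort(t)
    ts = np.round(t * 1e9).astype(np.int64)
    ts = np.unique(ts)
    vals = rng.normal(size=len(ts))
    return pf.TimestampedStream(device, metric, "u", rate_hz, ts, vals)
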