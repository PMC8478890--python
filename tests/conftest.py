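import numpy as np
import pytest

from walkrisk.cohort import SimulationConfig, VolunteerProfile, WalkRecording


def make_recording(
    volunteer_id="V0000",
    hr_bpm=None,
    pm25=None,
    pm10=None,
    labels=None,
    pm_interval=60.0,
):
    """Hand-built recording: 1 Hz heart rate, 1-min PM, per-interval labels."""
    hr_bpm = np.asarray(hr_bpm, dtype=float)
    n_pm = int(np.ceil(hr_bpm.size / pm_interval))
    if pm25 is None:
        pm25 = np.full(n_pm, 100.0)
    pm25 = np.asarray(pm25, dtype=float)
    if pm10 is None:
        pm10 = pm25 * 1.5 + 20.0
    if labels is None:
        labels = np.zeros(pm25.size, dtype=np.int64)
    return WalkRecording(
        volunteer_id=volunteer_id,
        hr_time=np.arange(hr_bpm.size, dtype=float),
        hr_bpm=hr_bpm,
        pm_time=np.arange(pm25.size, dtype=float) * pm_interval,
        pm25=pm25,
        pm10=np.asarray(pm10, dtype=float),
        labels=np.asarray(labels, dtype=np.int64),
    )


def make_profile(volunteer_id="V0000", gender="male", age_group="youth",
                 height=1.75, weight=70.0, baseline_hr=75.0):
    return VolunteerProfile(volunteer_id, gender, age_group, height, weight, baseline_hr)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        group_sizes={
            ("male", "youth"): 6,
            ("female", "youth"): 5,
            ("male", "middle_aged"): 5,
            ("female", "middle_aged"): 4,
        },
        walk_duration=1800.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from walkrisk.cohort import simulate_cohort

    return simulate_cohort(small_config)
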