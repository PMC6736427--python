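import numpy as np
import pytest
from hypothesis import settings

import chronofeed as cf

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def pair_fed_policy():
    return cf.AllowancePolicy(control_tdfi=24.0)


@pytest.fixture
def grazing_schedule(pair_fed_policy):
    return cf.build_grazing_schedule(policy=pair_fed_policy)


@pytest.fixture
def meal_schedule():
    return cf.build_meal_schedule()


@pytest.fixture
def rat():
    return cf.rat_model()


@pytest.fixture
def mouse():
    return cf.mouse_model()


def assign_events_to_windows(events, schedule, days):
    """Per-(day, window) event sums; shared helper for compliance checks."""
    t = events["time_min"].to_numpy()
    g = events["grams"].to_numpy()
    sums = {}
    for day in range(days):
        for wi, w in enumerate(schedule.windows):
            t0 = day * 1440.0 + (w.start - 360.0) % 1440.0
            sel = (t - 1.5 >= t0 - 1e-9) & (t - 1.5 < t0 + w.duration - 1e-9)
            sums[(day, wi)] = float(g[sel].sum())
    return sums


@pytest.fixture
def window_event_sums():
    return assign_events_to_windows
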