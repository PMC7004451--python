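import datetime as dt

import numpy as np
import pandas as pd
import pytest

from heatpm.simulate import TrueModel, generate_monitors, generate_subjects, generate_weather


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated world: 2 stations, 3 monitors, 300 subjects, 3 years."""
    stations = [("ST0", 32.0, -96.0), ("ST1", 34.0, -94.0)]
    monitors = [("M0", 32.1, -96.1), ("M1", 33.9, -94.2), ("M2", 31.5, -95.0)]
    start, end = dt.date(2000, 1, 1), dt.date(2002, 12, 31)
    weather = generate_weather(stations, start, end, seed=42)
    pm = generate_monitors(monitors, start, end, missing_rate=0.05, seed=43)
    subjects = generate_subjects(
        300, residence_box=(31.0, 34.5, -96.5, -93.5),
        edd_range=(dt.date(2001, 1, 1), dt.date(2002, 6, 30)), seed=44)
    return {"weather": weather, "monitors": pm, "subjects": subjects}


@pytest.fixture(scope="session")
def null_model():
    return TrueModel(intercept=-1.5, beta_pm=np.log(1.5), beta_ehe=np.log(1.3),
                     beta_interaction=0.0)


@pytest.fixture(scope="session")
def interaction_model():
    return TrueModel.from_joint_ors(-1.5, or10=1.5, or01=1.2, or11=2.2)
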