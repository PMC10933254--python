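import numpy as np
import pandas as pd
import pytest

from copd_engage import diary
from copd_engage.synthetic import SimulatedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240312)


@pytest.fixture
def tiny_symptoms():
    return diary.validate_symptoms(
        pd.DataFrame(
            {
                "user_id": ["u1", "u1", "u2"],
                "date": ["2021-01-01", "2021-01-03", "2021-01-01"],
                "score": [2, 3, 1],
            }
        )
    )


@pytest.fixture
def tiny_medications():
    return diary.validate_medications(
        pd.DataFrame(
            {
                "user_id": ["u1", "u2"],
                "drug_class": ["rescue_pack", "saba"],
                "use_date": ["2021-02-01", "2021-01-01"],
                "entry_date": ["2021-02-02", "2021-01-01"],
                "course_length": [5, None],
                "daily_count": [None, 3],
            }
        )
    )


def random_series(rng, *, series_id="s0", group="g", p_report=0.5,
                  course_length=5) -> SimulatedSeries:
    """A random exacerbation-aligned series for property tests."""
    records = {}
    for d in range(-70, 71):
        if rng.random() < p_report:
            records[d] = int(rng.integers(1, 5))
    return SimulatedSeries(series_id=series_id, group=group, records=records,
                           course_length=course_length)
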