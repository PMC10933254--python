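"""Rolling-window feature vectors and short-horizon exacerbation labels.

One prediction instance is built per day from 55 days before onset (so the
15-day trailing window is always complete) to 70 days after, skipping the
days of the exacerbation course itself.  Features summarise registered
symptom scores in trailing windows of 4, 8 and 15 days (mean, sample
standard deviation, count, min, max); days without reports simply contribute
nothing, so features other than the count are absent (NaN) when the window
holds no reports.  The label marks whether onset (day 0) falls within the
next three days.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import OFFSET_MAX, OFFSET_MIN, SimulatedSeries

__all__ = [
    "WINDOWS",
    "HORIZON_DAYS",
    "INSTANCE_START",
    "INSTANCE_END",
    "FEATURE_COLUMNS",
    "window_features",
    "build_instances",
    "build_instance_table",
]

WINDOWS = (4, 8, 15)
HORIZON_DAYS = 3
INSTANCE_START = -55
INSTANCE_END = 70

_STATS = ("mean", "sd", "count", "min", "max")
FEATURE_COLUMNS = tuple(f"score_{stat}_{w}d" for w in WINDOWS for stat in _STATS)


def window_features(
    records: Mapping[int, int], day_offset: int, w: int
) -> tuple[float, float, int, float, float]:
    """Summary statistics of registered scores in a trailing window.

    The window covers offsets ``[day_offset - w + 1, day_offset]``
    inclusive.  Returns ``(mean, sd, count, min, max)`` where ``sd`` is the
    sample standard deviation (NaN below two reports) and all statistics
    except the count are NaN when the window holds no reports.
    """
    if w not in WINDOWS:
        raise ValueError(f"window length {w} not in {WINDOWS}")
    values = [float(records[d]) for d in range(day_offset - w + 1, day_offset + 1)
              if d in records]
    count = len(values)
    if count == 0:
        return (math.nan, math.nan, 0, math.nan, math.nan)
    arr = np.asarray(values)
    sd = float(np.std(arr, ddof=1)) if count >= 2 else math.nan
    return (float(arr.mean()), sd, count, float(arr.min()), float(arr.max()))


def build_instances(
    series: SimulatedSeries,
    *,
    windows: Sequence[int] = WINDOWS,
    horizon: int = HORIZON_DAYS,
    start: int = INSTANCE_START,
    end: int = INSTANCE_END,
    reporting_days_only: bool = False,
) -> pd.DataFrame:
    """Build labelled prediction instances for one exacerbation-aligned series.

    One instance per offset in ``[start, end]``, excluding the days of the
    exacerbation course (offsets ``0 .. course_length - 1``).  The label is
    1 iff onset occurs within the next ``horizon`` days, i.e. at offsets
    ``-horizon .. -1``.  With ``reporting_days_only`` instances are emitted
    only for days carrying a registered score.
    """
    if start - min(windows, default=0) + 1 < OFFSET_MIN or end > OFFSET_MAX:
        raise ValueError("series span -70..+70 cannot cover requested instances")
    full = pd.Series(
        [series.records.get(d, np.nan) for d in range(OFFSET_MIN, OFFSET_MAX + 1)],
        index=range(OFFSET_MIN, OFFSET_MAX + 1),
        dtype=float,
    )
    excluded = set(range(0, series.course_length))
    offsets = [d for d in range(start, end + 1) if d not in excluded]
    if reporting_days_only:
        offsets = [d for d in offsets if d in series.records]

    data: dict[str, list] = {
        "series_id": [series.series_id] * len(offsets),
        "group": [series.group] * len(offsets),
        "day_offset": offsets,
    }
    for w in windows:
        roll = full.rolling(window=w, min_periods=1)
        mean = roll.mean()
        sd = roll.std(ddof=1)
        cnt = full.rolling(window=w, min_periods=0).count()
        mn = roll.min()
        mx = roll.max()
        data[f"score_mean_{w}d"] = mean.loc[offsets].to_numpy()
        data[f"score_sd_{w}d"] = sd.loc[offsets].to_numpy()
        data[f"score_count_{w}d"] = cnt.loc[offsets].to_numpy().astype(int)
        data[f"score_min_{w}d"] = mn.loc[offsets].to_numpy()
        data[f"score_max_{w}d"] = mx.loc[offsets].to_numpy()
    data["label"] = [1 if -horizon <= d <= -1 else 0 for d in offsets]
    return pd.DataFrame(data)


def build_instance_table(
    series_collection: Sequence[SimulatedSeries], **kwargs
) -> pd.DataFrame:
    """Concatenate :func:`build_instances` over a collection of series."""
    if len(series_collection) == 0:
        return pd.DataFrame(
            columns=["series_id", "group", "day_offset", *FEATURE_COLUMNS, "label"]
        )
    frames = [build_instances(s, **kwargs) for s in series_collection]
    return pd.concat(frames, ignore_index=True)
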