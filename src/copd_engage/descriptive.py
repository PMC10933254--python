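"""Event-aligned descriptive analyses.

Compares symptom-score and reliever-usage profiles around first versus
subsequent in-app exacerbations, tests their pooled score distributions with
a Pearson chi-square, measures the lag between the reliever-usage peak and
the symptom-score peak, and cross-tabulates engagement against GOLD 2022
combined-assessment groups.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import OFFSET_MAX, OFFSET_MIN, OFFSETS

__all__ = [
    "event_aligned_profiles",
    "chi_square_scores",
    "peak_lag",
    "gold_group",
    "engagement_by_gold",
]

# GOLD 2022 combined-assessment thresholds
GOLD_CAT_MIN = 10
GOLD_MMRC_MIN = 2
GOLD_MODERATE_MIN = 2
GOLD_HOSPITALISED_MIN = 1


def _aligned_arrays(
    events: pd.DataFrame,
    symptoms: pd.DataFrame,
    medications: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-event x per-offset score / SABA-count matrices (NaN = no record)."""
    n = len(events)
    score = np.full((n, len(OFFSETS)), np.nan)
    saba = np.zeros((n, len(OFFSETS)))
    sym_by_user = dict(tuple(symptoms.groupby("user_id", sort=False)))
    saba_rows = medications[medications["drug_class"] == "saba"]
    saba_by_user = dict(tuple(saba_rows.groupby("user_id", sort=False)))
    for i, ev in enumerate(events.itertuples(index=False)):
        rows = sym_by_user.get(ev.user_id)
        if rows is not None:
            offs = (rows["date"] - ev.onset_date).dt.days.to_numpy()
            keep = (offs >= OFFSET_MIN) & (offs <= OFFSET_MAX)
            score[i, offs[keep] - OFFSET_MIN] = rows["score"].to_numpy()[keep]
        rows = saba_by_user.get(ev.user_id)
        if rows is not None:
            offs = (rows["use_date"] - ev.onset_date).dt.days.to_numpy()
            keep = (offs >= OFFSET_MIN) & (offs <= OFFSET_MAX)
            counts = rows["daily_count"].fillna(0).to_numpy(dtype=float)[keep]
            np.add.at(saba[i], offs[keep] - OFFSET_MIN, counts)
    first = events["first_for_user"].to_numpy(dtype=bool)
    return score[first], saba[first], score[~first], saba[~first]


def _profile_frame(cohort: str, score: np.ndarray, saba: np.ndarray) -> pd.DataFrame:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_score = np.nanmean(score, axis=0)  # all-NaN offsets stay NaN
    return pd.DataFrame(
        {
            "cohort": cohort,
            "day_offset": OFFSETS,
            "mean_score": mean_score,
            "mean_saba_count": saba.mean(axis=0),
            "pct_reporting": 100.0 * np.mean(~np.isnan(score), axis=0),
        }
    )


def event_aligned_profiles(
    events: pd.DataFrame,
    symptoms: pd.DataFrame,
    medications: pd.DataFrame,
) -> pd.DataFrame:
    """Offset-indexed mean score, mean SABA count and reporting percentage.

    Events are split into ``first`` (the user's first registered
    exacerbation) and ``subsequent`` cohorts.  Score means are taken over
    registered values only; SABA counts default to zero on days without a
    record.  Raises ``ValueError`` when either cohort is empty.
    """
    if events.empty:
        raise ValueError("event_aligned_profiles requires events")
    sf, af, ss, as_ = _aligned_arrays(events, symptoms, medications)
    if len(sf) == 0:
        raise ValueError("no first-for-user events in input")
    if len(ss) == 0:
        raise ValueError("no subsequent events in input")
    return pd.concat(
        [_profile_frame("first", sf, af), _profile_frame("subsequent", ss, as_)],
        ignore_index=True,
    )


def chi_square_scores(
    scores_first: Sequence[int],
    scores_subsequent: Sequence[int],
) -> tuple[float, int, float]:
    """Pearson chi-square comparing pooled daily score distributions.

    Scores from the two cohorts are tabulated into a score-category x
    cohort contingency table (categories with zero total count are pooled
    into the adjacent category by dropping the empty row, which is
    equivalent for the statistic).  Returns (statistic, df, p).
    """
    a = pd.Series(list(scores_first)).value_counts().reindex(
        [1, 2, 3, 4], fill_value=0
    )
    b = pd.Series(list(scores_subsequent)).value_counts().reindex(
        [1, 2, 3, 4], fill_value=0
    )
    table = np.column_stack([a.to_numpy(), b.to_numpy()])
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        raise ValueError(
            "chi-square needs at least two score categories and both cohorts; "
            "pool sparse categories before testing"
        )
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return (float(stat), int(df), float(p))


def peak_lag(
    saba_curve: Mapping[int, float] | pd.Series,
    score_curve: Mapping[int, float] | pd.Series,
) -> int:
    """Days by which the symptom-score peak trails the reliever-usage peak.

    Computed as ``argmax(score) - argmax(saba)`` over the shared offsets;
    ties resolve to the earliest offset.
    """
    saba = pd.Series(dict(saba_curve)).sort_index()
    score = pd.Series(dict(score_curve)).sort_index()
    if saba.empty or score.empty:
        raise ValueError("peak_lag requires non-empty curves")
    saba_peak = int(saba.index[int(np.argmax(saba.to_numpy()))])
    score_peak = int(score.index[int(np.argmax(score.to_numpy()))])
    return score_peak - saba_peak


def gold_group(
    cat_score: Optional[int] = None,
    mmrc: Optional[int] = None,
    moderate_exacerbations_last_year: int = 0,
    hospitalisations_last_year: int = 0,
) -> str:
    """GOLD 2022 combined-assessment group (A-D) from history and symptoms.

    High risk: >= 2 moderate exacerbations or >= 1 hospitalisation in the
    last year.  High symptoms: CAT >= 10 or mMRC >= 2.  Returns
    ``undetermined`` when both symptom measures are missing.
    """
    cat_missing = cat_score is None or pd.isna(cat_score)
    mmrc_missing = mmrc is None or pd.isna(mmrc)
    if cat_missing and mmrc_missing:
        return "undetermined"
    high_risk = (
        (moderate_exacerbations_last_year or 0) >= GOLD_MODERATE_MIN
        or (hospitalisations_last_year or 0) >= GOLD_HOSPITALISED_MIN
    )
    high_symptom = (not cat_missing and cat_score >= GOLD_CAT_MIN) or (
        not mmrc_missing and mmrc >= GOLD_MMRC_MIN
    )
    if high_risk:
        return "D" if high_symptom else "C"
    return "B" if high_symptom else "A"


def gold_groups_for_profiles(profiles: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`gold_group` over a validated profile table."""
    def _one(row):
        return gold_group(
            cat_score=row.get("cat_score"),
            mmrc=row.get("mmrc"),
            moderate_exacerbations_last_year=row.get(
                "moderate_exacerbations_last_year", 0) or 0,
            hospitalisations_last_year=row.get(
                "hospitalisations_last_year", 0) or 0,
        )
    return profiles.apply(_one, axis=1)


def engagement_by_gold(
    engagement_class: Mapping[str, str] | pd.Series,
    gold: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Percentage of users in each GOLD group per engagement class.

    Both inputs map user id -> label and must cover the same users.  Rows
    (engagement classes) sum to 100 within rounding.
    """
    eng = pd.Series(dict(engagement_class))
    gld = pd.Series(dict(gold))
    if eng.empty:
        raise ValueError("engagement_by_gold requires at least one user")
    if set(eng.index) != set(gld.index):
        raise ValueError("engagement and GOLD labels must cover the same users")
    table = pd.crosstab(eng, gld.loc[eng.index])
    table.index.name = "engagement_class"
    table.columns.name = "gold_group"
    return 100.0 * table.div(table.sum(axis=1), axis=0)
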