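"""Engagement classification, transitional behaviour and self-report quality.

App usage around an exacerbation is the fraction of days with a registered
symptom score out of the window length.  Events are classed on the 70-day
pre-onset window (frequent >= 66%, intermediate 33--66%, infrequent < 33%);
a non-frequent event whose 21-day pre-onset fraction classifies higher is
"engaged near exacerbation".  Pre-onset score sequences are additionally
labelled for predictive quality (fixed reporting vs reporting-with-signal),
and post-onset windows are screened for disengagement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_ORDER",
    "EngagementProfile",
    "usage_fraction",
    "classify_engagement",
    "classify_transition",
    "classify_quality",
    "flag_post_disengagement",
    "build_engagement_profiles",
    "engagement_summary",
    "model_group",
    "MODEL_GROUPS",
]

#: Ordinal engagement classes, least to most engaged.
CLASS_ORDER = ("infrequent", "intermediate", "frequent")

#: Class boundaries exactly as printed: frequent closed at 0.66, infrequent
#: open at 0.33.
FREQUENT_MIN = 0.66
INTERMEDIATE_MIN = 0.33

PRE_WINDOW = (-70, -1)
PRE21_WINDOW = (-21, -1)
POST_WINDOW = (1, 70)

#: The five engagement groups evaluated by the risk model.
MODEL_GROUPS = (
    "frequent",
    "intermediate_consistent",
    "intermediate_engaged_near_exacerbation",
    "infrequent_consistent",
    "infrequent_engaged_near_exacerbation",
)


@dataclass(frozen=True)
class EngagementProfile:
    """Engagement and data-quality labels for one exacerbation window."""

    user_id: str
    onset_date: pd.Timestamp
    pre70_fraction: float
    post70_fraction: float
    pre21_fraction: float
    class70: str
    class21: str
    transition: str
    quality: str
    post_disengaged: bool
    first_for_user: bool = False
    retrospective: Optional[bool] = None


def usage_fraction(offsets: Iterable[int], window: tuple[int, int]) -> float:
    """Fraction of window days carrying a registered symptom score.

    ``offsets`` are day offsets of the user's reports relative to onset
    (day 0); ``window`` is an inclusive [start, end] offset pair.
    """
    start, end = window
    length = end - start + 1
    if length < 1:
        raise ValueError(f"window {window} has non-positive length")
    days = {int(d) for d in offsets if start <= int(d) <= end}
    return len(days) / length


def classify_engagement(fraction: float) -> str:
    """Map a usage fraction onto {infrequent, intermediate, frequent}."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"usage fraction {fraction} outside [0, 1]")
    if fraction >= FREQUENT_MIN:
        return "frequent"
    if fraction < INTERMEDIATE_MIN:
        return "infrequent"
    return "intermediate"


def classify_transition(class70: str, pre21_fraction: float) -> str:
    """Detect transitional engagement in the 21 days before onset.

    An event is ``engaged_near_exacerbation`` iff its 21-day class strictly
    exceeds its 70-day class; frequent events are always consistent.
    """
    if class70 not in CLASS_ORDER:
        raise ValueError(f"unknown engagement class {class70!r}")
    class21 = classify_engagement(pre21_fraction)
    if CLASS_ORDER.index(class21) > CLASS_ORDER.index(class70):
        return "engaged_near_exacerbation"
    return "consistent"


def classify_quality(
    pre_scores: Sequence[tuple[int, int]],
    *,
    min_reports: int = 5,
    signal_rise: float = 0.5,
    recent_window: tuple[int, int] = (-7, -1),
) -> str:
    """Label the predictive quality of pre-onset self-reports.

    ``pre_scores`` is a sequence of (day_offset, score) pairs drawn from the
    70-day pre-window.  Returns ``undetermined`` below ``min_reports``
    reports, ``fixed_reporting`` when a single distinct score value is
    registered, ``reporting_with_signal`` when the final-week mean exceeds
    the earlier baseline mean by at least ``signal_rise``, else ``neither``.
    """
    pairs = [(int(d), int(s)) for d, s in pre_scores
             if PRE_WINDOW[0] <= int(d) <= PRE_WINDOW[1]]
    if len(pairs) < min_reports:
        return "undetermined"
    scores = [s for _, s in pairs]
    if len(set(scores)) == 1:
        return "fixed_reporting"
    lo, hi = recent_window
    recent = [s for d, s in pairs if lo <= d <= hi]
    baseline = [s for d, s in pairs if d < lo]
    if recent and baseline:
        if float(np.mean(recent)) - float(np.mean(baseline)) >= signal_rise:
            return "reporting_with_signal"
    return "neither"


def flag_post_disengagement(
    records: Mapping[int, int],
    *,
    gap_days: int = 14,
    gap_start_window: tuple[int, int] = (1, 14),
) -> bool:
    """Screen an exacerbation window for post-event disengagement.

    ``records`` maps day offsets (-70..+70) to scores.  True iff any score
    of 4 (emergency care) is registered anywhere in the window, or at least
    ``gap_days`` consecutive unreported days begin within days +1..+14.
    """
    if any(int(s) == 4 for d, s in records.items() if -70 <= int(d) <= 70):
        return True
    reported = {int(d) for d in records}
    lo, hi = gap_start_window
    for start in range(lo, hi + 1):
        if all(start + i not in reported for i in range(gap_days)):
            return True
    return False


def _user_offsets(symptoms: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {uid: grp for uid, grp in symptoms.groupby("user_id", sort=False)}


def build_engagement_profiles(
    events: pd.DataFrame,
    symptoms: pd.DataFrame,
    *,
    min_reports: int = 5,
    signal_rise: float = 0.5,
    gap_days: int = 14,
) -> pd.DataFrame:
    """Label every exacerbation event with its engagement profile.

    ``events`` is the output of :func:`copd_engage.diary.identify_exacerbations`
    and ``symptoms`` a validated symptom table.  Returns one row per event.
    """
    by_user = _user_offsets(symptoms)
    rows = []
    for ev in events.itertuples(index=False):
        user_rows = by_user.get(ev.user_id)
        if user_rows is None:
            offsets = np.array([], dtype=int)
            scores = np.array([], dtype=int)
        else:
            offsets = (user_rows["date"] - ev.onset_date).dt.days.to_numpy()
            scores = user_rows["score"].to_numpy()
        in_window = (offsets >= -70) & (offsets <= 70)
        window_records = dict(zip(offsets[in_window], scores[in_window]))

        pre70 = usage_fraction(offsets, PRE_WINDOW)
        post70 = usage_fraction(offsets, POST_WINDOW)
        pre21 = usage_fraction(offsets, PRE21_WINDOW)
        class70 = classify_engagement(pre70)
        class21 = classify_engagement(pre21)
        pre_pairs = [(d, s) for d, s in window_records.items() if d <= -1]
        rows.append(
            {
                "user_id": ev.user_id,
                "onset_date": ev.onset_date,
                "pre70_fraction": pre70,
                "post70_fraction": post70,
                "pre21_fraction": pre21,
                "class70": class70,
                "class21": class21,
                "transition": classify_transition(class70, pre21),
                "quality": classify_quality(
                    pre_pairs, min_reports=min_reports, signal_rise=signal_rise
                ),
                "post_disengaged": flag_post_disengagement(
                    window_records, gap_days=gap_days
                ),
                "first_for_user": bool(ev.first_for_user),
                "retrospective": ev.retrospective,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["retrospective"] = out["retrospective"].astype("boolean")
    return out


def model_group(class70: str, transition: str) -> str:
    """Map (class70, transition) to one of the five evaluated groups."""
    if class70 == "frequent":
        return "frequent"
    return f"{class70}_{transition}"


def engagement_summary(profiles: pd.DataFrame) -> dict:
    """Cohort summary: counts and percentages per class/transition/quality cell.

    Percentages are over all events; per-class transition and quality shares
    are over that class.  Raises ``ValueError`` on empty input.  Counts are
    conserved: class counts sum to the number of profiles.
    """
    if profiles is None or len(profiles) == 0:
        raise ValueError("engagement_summary requires at least one profile")
    n = len(profiles)
    summary: dict = {"n_events": n, "classes": {}, "quality": {}}
    class_counts = profiles["class70"].value_counts()
    for cls in CLASS_ORDER[::-1]:
        count = int(class_counts.get(cls, 0))
        cls_rows = profiles[profiles["class70"] == cls]
        trans = int((cls_rows["transition"] == "engaged_near_exacerbation").sum())
        summary["classes"][cls] = {
            "count": count,
            "pct": 100.0 * count / n,
            "engaged_near_exacerbation": {
                "count": trans,
                "pct_of_class": 100.0 * trans / count if count else 0.0,
            },
        }
    for q, count in profiles["quality"].value_counts().items():
        summary["quality"][q] = {"count": int(count), "pct": 100.0 * count / n}

    nonfrequent = profiles[profiles["class70"] != "frequent"]
    n_nonfreq = len(nonfrequent)
    n_trans = int(
        (nonfrequent["transition"] == "engaged_near_exacerbation").sum()
    )
    summary["nonfrequent"] = {
        "count": n_nonfreq,
        "transitional_count": n_trans,
        "transitional_pct": 100.0 * n_trans / n_nonfreq if n_nonfreq else 0.0,
    }
    summary["post_disengaged"] = {
        "count": int(profiles["post_disengaged"].sum()),
        "pct": 100.0 * float(profiles["post_disengaged"].mean()),
    }
    if "retrospective" in profiles.columns:
        retro = profiles["retrospective"]
        summary["retrospective"] = {
            "count": int((retro == True).sum()),  # noqa: E712 (nullable boolean)
            "undetermined": int(retro.isna().sum()),
        }
    return summary
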