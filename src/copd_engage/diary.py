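"""Domain types, diary-table ingestion, and exacerbation event identification.

Diary data arrive as three tidy CSV tables (ISO-8601 dates throughout):

* ``symptoms.csv``    -- one row per user-day self-assessed score (1--4);
* ``medications.csv`` -- medication diary entries (SABA doses, rescue-pack
  courses, routine medication);
* ``profiles.csv``    -- one row per user with demographics, CAT, mMRC and
  annual exacerbation history.

An exacerbation event is a rescue-pack course with a well-defined start date:
courses longer than 10 days are treated as weaning/maintenance prescriptions
and excluded, and overlapping or abutting courses are merged (the merged span
must itself fit in 10 days to count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SymptomRecord",
    "MedicationRecord",
    "UserProfile",
    "ExacerbationEvent",
    "DiaryTables",
    "DiaryValidationError",
    "MAX_COURSE_DAYS",
    "RETROSPECTIVE_GAP_DAYS",
    "read_diaries",
    "validate_symptoms",
    "validate_medications",
    "validate_profiles",
    "identify_exacerbations",
    "flag_retrospective",
]

#: Rescue-pack courses longer than this are excluded from event detection.
MAX_COURSE_DAYS = 10

#: An event is "retrospective" when its in-app entry lags onset by more days.
RETROSPECTIVE_GAP_DAYS = 10

VALID_SCORES = frozenset({1, 2, 3, 4})
DRUG_CLASSES = frozenset({"saba", "rescue_pack", "routine"})


class DiaryValidationError(ValueError):
    """Raised when a diary table violates the schema or its invariants."""


@dataclass(frozen=True)
class SymptomRecord:
    """One user-day self-assessed symptom score on the 4-point scale.

    A score of 4 means the user needed to seek emergency care.
    """

    user_id: str
    date: pd.Timestamp
    score: int

    def __post_init__(self) -> None:
        if self.score not in VALID_SCORES:
            raise DiaryValidationError(f"score {self.score} outside 1..4")


@dataclass(frozen=True)
class MedicationRecord:
    """A medication diary entry.

    ``use_date`` is the date the dose/course is reported for; ``entry_date``
    is when the row was created in-app.  Back- and forward-dating are both
    allowed.  ``course_length`` is present iff the record is a rescue pack;
    ``daily_count`` iff it is a SABA.
    """

    user_id: str
    drug_class: str
    use_date: pd.Timestamp
    entry_date: Optional[pd.Timestamp] = None
    course_length: Optional[int] = None
    daily_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise DiaryValidationError(f"unknown drug class {self.drug_class!r}")
        has_course = self.course_length is not None
        if (self.drug_class == "rescue_pack") != has_course:
            raise DiaryValidationError(
                "course_length must be present iff drug_class is rescue_pack"
            )
        if has_course and self.course_length < 1:
            raise DiaryValidationError("course_length must be >= 1")
        if self.daily_count is not None and self.daily_count < 0:
            raise DiaryValidationError("daily_count must be >= 0")


@dataclass(frozen=True)
class UserProfile:
    """Per-user baseline characteristics used for GOLD grouping."""

    user_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    cat_score: Optional[int] = None
    mmrc: Optional[int] = None
    moderate_exacerbations_last_year: int = 0
    hospitalisations_last_year: int = 0

    def __post_init__(self) -> None:
        if self.cat_score is not None and not 0 <= self.cat_score <= 40:
            raise DiaryValidationError(f"CAT score {self.cat_score} outside 0..40")
        if self.mmrc is not None and not 0 <= self.mmrc <= 4:
            raise DiaryValidationError(f"mMRC {self.mmrc} outside 0..4")


@dataclass(frozen=True)
class ExacerbationEvent:
    """An exacerbation anchored at the first day of a rescue-pack course.

    ``onset_date`` is day 0 of all offset arithmetic; the pre-window is days
    -70..-1 and the post-window +1..+70.  ``retrospective`` is ``None`` when
    the in-app entry date is unknown (flag undetermined, not false).
    """

    user_id: str
    onset_date: pd.Timestamp
    course_length: int
    first_for_user: bool = False
    retrospective: Optional[bool] = None

    def __post_init__(self) -> None:
        if not 1 <= self.course_length <= MAX_COURSE_DAYS:
            raise DiaryValidationError(
                f"course_length {self.course_length} outside 1..{MAX_COURSE_DAYS}"
            )


class DiaryTables(NamedTuple):
    symptoms: pd.DataFrame
    medications: pd.DataFrame
    profiles: pd.DataFrame


# ---------------------------------------------------------------------------
# ingestion / validation
# ---------------------------------------------------------------------------

def _parse_dates(frame: pd.DataFrame, column: str, *, table: str,
                 allow_missing: bool = False) -> pd.Series:
    raw = frame[column]
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    missing_raw = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = parsed.isna() & ~missing_raw
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DiaryValidationError(
            f"{table}: cannot parse {column}={raw.iloc[row]!r} at row {row}"
        )
    if not allow_missing and parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise DiaryValidationError(f"{table}: missing {column} at row {row}")
    return parsed


def validate_symptoms(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a raw symptom table (user_id, date, score)."""
    required = {"user_id", "date", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise DiaryValidationError(f"symptoms: missing columns {sorted(missing)}")
    out = frame.copy()
    out["user_id"] = out["user_id"].astype(str)
    out["date"] = _parse_dates(out, "date", table="symptoms")
    scores = pd.to_numeric(out["score"], errors="coerce")
    bad = scores.isna() | ~scores.isin(list(VALID_SCORES))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DiaryValidationError(
            f"symptoms: score {frame['score'].iloc[row]!r} at row {row} "
            "outside {1,2,3,4}"
        )
    out["score"] = scores.astype(int)
    dup = out.duplicated(subset=["user_id", "date"], keep=False)
    if dup.any():
        key = out.loc[dup, ["user_id", "date"]].iloc[0]
        raise DiaryValidationError(
            f"symptoms: duplicate record for user {key['user_id']} on "
            f"{key['date'].date()}"
        )
    return out.reset_index(drop=True)


def validate_medications(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a raw medication table."""
    required = {"user_id", "drug_class", "use_date"}
    missing = required - set(frame.columns)
    if missing:
        raise DiaryValidationError(f"medications: missing columns {sorted(missing)}")
    out = frame.copy()
    out["user_id"] = out["user_id"].astype(str)
    out["drug_class"] = out["drug_class"].astype(str).str.strip().str.lower()
    bad_class = ~out["drug_class"].isin(list(DRUG_CLASSES))
    if bad_class.any():
        row = int(np.flatnonzero(bad_class.to_numpy())[0])
        raise DiaryValidationError(
            f"medications: unknown drug_class {out['drug_class'].iloc[row]!r} "
            f"at row {row}"
        )
    out["use_date"] = _parse_dates(out, "use_date", table="medications")
    if "entry_date" in out.columns:
        out["entry_date"] = _parse_dates(
            out, "entry_date", table="medications", allow_missing=True
        )
    else:
        out["entry_date"] = pd.NaT
    for col in ("course_length", "daily_count"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
        else:
            out[col] = pd.array([pd.NA] * len(out), dtype="Int64")
    is_rescue = out["drug_class"] == "rescue_pack"
    if (is_rescue & out["course_length"].isna()).any():
        raise DiaryValidationError("medications: rescue_pack row lacks course_length")
    if (~is_rescue & out["course_length"].notna()).any():
        raise DiaryValidationError(
            "medications: course_length only valid on rescue_pack rows"
        )
    if (out.loc[is_rescue, "course_length"] < 1).any():
        raise DiaryValidationError("medications: course_length must be >= 1")
    if (out["daily_count"].dropna() < 0).any():
        raise DiaryValidationError("medications: daily_count must be >= 0")
    return out.reset_index(drop=True)


def validate_profiles(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a raw user-profile table."""
    if "user_id" not in frame.columns:
        raise DiaryValidationError("profiles: missing column user_id")
    out = frame.copy()
    out["user_id"] = out["user_id"].astype(str)
    if out["user_id"].duplicated().any():
        raise DiaryValidationError("profiles: duplicate user_id")
    for col, lo, hi in (("cat_score", 0, 40), ("mmrc", 0, 4)):
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DiaryValidationError(
                    f"profiles: {col}={frame[col].iloc[row]!r} at row {row} "
                    f"outside {lo}..{hi}"
                )
            out[col] = vals.astype("Int64")
    for col in ("moderate_exacerbations_last_year", "hospitalisations_last_year"):
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise DiaryValidationError(f"profiles: negative {col}")
            out[col] = vals.astype("Int64")
    return out.reset_index(drop=True)


def read_diaries(symptoms_path, medications_path, profiles_path) -> DiaryTables:
    """Read and validate the three diary CSVs.

    Raises :class:`DiaryValidationError` on malformed dates, out-of-range
    scores, or duplicate (user, date) symptom rows.
    """
    symptoms = validate_symptoms(pd.read_csv(symptoms_path))
    medications = validate_medications(pd.read_csv(medications_path))
    profiles = validate_profiles(pd.read_csv(profiles_path))
    return DiaryTables(symptoms, medications, profiles)


# ---------------------------------------------------------------------------
# event identification
# ---------------------------------------------------------------------------

def flag_retrospective(onset_date, entry_date) -> Optional[bool]:
    """True iff the in-app entry lags onset by more than 10 days.

    Returns ``None`` (undetermined) when the entry date is missing; a
    boundary lag of exactly 10 days is not retrospective.
    """
    if entry_date is None or pd.isna(entry_date):
        return None
    gap = (pd.Timestamp(entry_date) - pd.Timestamp(onset_date)).days
    return gap > RETROSPECTIVE_GAP_DAYS


def _merge_courses(courses: pd.DataFrame) -> list[dict]:
    """Merge overlapping/abutting rescue-pack courses of one user.

    Courses are intervals [use_date, use_date + length - 1]; chains whose
    intervals overlap or abut collapse into one span with onset at the
    earliest start.  Spans longer than MAX_COURSE_DAYS are dropped as
    weaning/maintenance prescriptions.
    """
    rows = courses.sort_values(["use_date", "course_length"]).to_dict("records")
    merged: list[dict] = []
    for row in rows:
        start = row["use_date"]
        end = start + pd.Timedelta(days=int(row["course_length"]) - 1)
        entry = row["entry_date"]
        if merged and start <= merged[-1]["end"] + pd.Timedelta(days=1):
            cur = merged[-1]
            cur["end"] = max(cur["end"], end)
            if pd.isna(cur["entry"]) or (not pd.isna(entry) and entry < cur["entry"]):
                cur["entry"] = entry
        else:
            merged.append({"start": start, "end": end, "entry": entry})
    out = []
    for span in merged:
        length = (span["end"] - span["start"]).days + 1
        if length <= MAX_COURSE_DAYS:
            out.append(
                {
                    "onset_date": span["start"],
                    "course_length": length,
                    "entry_date": span["entry"],
                }
            )
    return out


def identify_exacerbations(medications: pd.DataFrame) -> pd.DataFrame:
    """Identify exacerbation events from a validated medication table.

    Returns a frame with one row per qualifying rescue-pack course: columns
    ``user_id, onset_date, course_length, first_for_user, retrospective``
    (retrospective is a nullable boolean), sorted by user then onset.
    Idempotent and independent of input row order.
    """
    columns = ["user_id", "onset_date", "course_length", "first_for_user",
               "retrospective"]
    empty = pd.DataFrame(columns=columns).astype(
        {"course_length": int, "first_for_user": bool, "retrospective": "boolean"}
    )
    rescue = medications[medications["drug_class"] == "rescue_pack"]
    if rescue.empty:
        return empty
    events = []
    for user_id, group in rescue.groupby("user_id", sort=True):
        for span in _merge_courses(group):
            events.append(
                {
                    "user_id": user_id,
                    "onset_date": span["onset_date"],
                    "course_length": span["course_length"],
                    "retrospective": flag_retrospective(
                        span["onset_date"], span["entry_date"]
                    ),
                }
            )
    if not events:
        return empty
    frame = pd.DataFrame(events).sort_values(["user_id", "onset_date"])
    frame["first_for_user"] = ~frame["user_id"].duplicated()
    frame["retrospective"] = frame["retrospective"].astype("boolean")
    return frame[columns].reset_index(drop=True)


def events_as_records(frame: pd.DataFrame) -> list[ExacerbationEvent]:
    """Convert an event frame into typed :class:`ExacerbationEvent` objects."""
    out = []
    for row in frame.itertuples(index=False):
        retro = None if pd.isna(row.retrospective) else bool(row.retrospective)
        out.append(
            ExacerbationEvent(
                user_id=row.user_id,
                onset_date=row.onset_date,
                course_length=int(row.course_length),
                first_for_user=bool(row.first_for_user),
                retrospective=retro,
            )
        )
    return out
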