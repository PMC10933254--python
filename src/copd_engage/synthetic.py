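"""Two-layer simulation of exacerbation-aligned symptom diaries.

Layer (a): :func:`generate_cohort` produces a raw synthetic cohort of diary
tables (symptoms, medications, profiles) with known ground truth.  Users are
drawn from engagement archetypes (infrequent / intermediate / frequent daily
reporting probability bands), may transition to elevated reporting in the 21
days before an exacerbation, show a prodromal rise of categorical symptom
scores before onset, and report reliever (SABA) usage whose mean peaks at
onset -- a fixed number of days before the symptom-score mean peaks.  Each
exacerbation is marked by a rescue-pack course starting at onset, optionally
entered in-app retrospectively.

Layer (b): :func:`fit_group_profile` fits day-offset-conditioned empirical
distributions (reporting probability and score category frequencies, pooled
over a +/-3-day bin) from a collection of exacerbation-aligned series, and
:func:`simulate_exacerbation_series` samples complete -70..+70 day series
directly from those distributions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OFFSET_MIN",
    "OFFSET_MAX",
    "OFFSETS",
    "CohortConfig",
    "EmpiricalGroupProfile",
    "SimulatedSeries",
    "generate_cohort",
    "series_from_events",
    "fit_group_profile",
    "simulate_exacerbation_series",
    "series_to_frame",
]

OFFSET_MIN = -70
OFFSET_MAX = 70
#: All day offsets of an exacerbation-aligned series (onset = 0).
OFFSETS = np.arange(OFFSET_MIN, OFFSET_MAX + 1)
N_OFFSETS = len(OFFSETS)
SCORE_VALUES = np.array([1, 2, 3, 4])


def _default_mix() -> dict:
    return {"infrequent": 0.25, "intermediate": 0.25, "frequent": 0.50}


def _default_transition() -> dict:
    return {"infrequent": 0.20, "intermediate": 0.25, "frequent": 0.0}


def _default_report_bands() -> dict:
    return {
        "infrequent": (0.08, 0.28),
        "intermediate": (0.38, 0.60),
        "frequent": (0.72, 0.97),
    }


def _default_near_onset_bands() -> dict:
    return {"infrequent": (0.60, 0.90), "intermediate": (0.78, 0.97)}


def _default_retrospective() -> dict:
    return {"infrequent": 0.70, "intermediate": 0.20, "frequent": 0.05}


def _default_events_per_user() -> dict:
    return {1: 0.55, 2: 0.30, 3: 0.15}


@dataclass
class CohortConfig:
    """Parameters of the raw synthetic cohort generator.

    ``engagement_mix`` gives archetype proportions; per-class daily
    reporting probabilities are drawn uniformly from ``report_prob_bands``.
    ``transition_prob`` is the per-class chance that a user reports at the
    elevated ``near_onset_bands`` rate during the 21 days before each onset.
    Symptom scores mix ``baseline_score_dist`` (scores 1..3) with
    ``elevated_score_dist`` (scores 1..4, emergency-care score included)
    along a prodromal ramp that peaks ``saba_lead_days`` after onset, while
    reliever usage peaks at onset itself.
    """

    n_users: int = 400
    engagement_mix: Mapping[str, float] = field(default_factory=_default_mix)
    transition_prob: Mapping[str, float] = field(default_factory=_default_transition)
    report_prob_bands: Mapping[str, tuple] = field(default_factory=_default_report_bands)
    near_onset_bands: Mapping[str, tuple] = field(default_factory=_default_near_onset_bands)
    baseline_score_dist: Sequence[float] = (0.55, 0.35, 0.10)
    elevated_score_dist: Sequence[float] = (0.02, 0.18, 0.65, 0.15)
    prodrome_days: int = 7
    prodrome_shift: float = 1.0
    first_event_shift_scale: float = 0.6
    saba_lead_days: int = 3
    recovery_days: int = 10
    saba_base_rate: float = 0.4
    saba_peak_rate: float = 4.0
    exacerbations_per_user: Mapping[int, float] = field(default_factory=_default_events_per_user)
    course_length_range: tuple = (3, 7)
    retrospective_prob: Mapping[str, float] = field(default_factory=_default_retrospective)
    transition_window_days: int = 21
    start_date: str = "2021-01-01"
    event_spacing_days: int = 170
    seed: int = 0

    def validate(self) -> None:
        mix = np.array([self.engagement_mix[c]
                        for c in ("infrequent", "intermediate", "frequent")])
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("engagement_mix must be non-negative and sum to 1")
        probs = np.array(list(self.exacerbations_per_user.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("exacerbations_per_user must be a distribution")
        for name, dist in (("baseline_score_dist", self.baseline_score_dist),
                           ("elevated_score_dist", self.elevated_score_dist)):
            arr = np.array(dist, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a distribution")
        for p in self.transition_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must be in [0, 1]")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "exacerbations_per_user" in kwargs:
            kwargs["exacerbations_per_user"] = {
                int(k): float(v) for k, v in kwargs["exacerbations_per_user"].items()
            }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class SimulatedSeries:
    """One exacerbation-aligned series: day offsets -70..+70, onset at 0."""

    series_id: str
    group: str
    records: dict[int, int]
    course_length: int = 5

    def __post_init__(self) -> None:
        for d in self.records:
            if not OFFSET_MIN <= d <= OFFSET_MAX:
                raise ValueError(f"offset {d} outside [{OFFSET_MIN}, {OFFSET_MAX}]")


@dataclass
class EmpiricalGroupProfile:
    """Day-offset-conditioned reporting and score distributions of one group.

    ``report_prob[i]`` is the share of source series registering a score at
    ``OFFSETS[i]``; ``score_dist[i]`` the categorical distribution over
    scores 1..4 at that offset, pooled over a +/-``bin_halfwidth``-day bin.
    """

    group: str
    report_prob: np.ndarray
    score_dist: np.ndarray
    n_source_series: int
    course_length_dist: dict[int, float] = field(default_factory=lambda: {5: 1.0})
    bin_halfwidth: int = 3

    def __post_init__(self) -> None:
        self.report_prob = np.asarray(self.report_prob, dtype=float)
        self.score_dist = np.asarray(self.score_dist, dtype=float)
        if self.report_prob.shape != (N_OFFSETS,):
            raise ValueError("report_prob must cover offsets -70..+70")
        if self.score_dist.shape != (N_OFFSETS, 4):
            raise ValueError("score_dist must be (141, 4)")
        if ((self.report_prob < 0) | (self.report_prob > 1)).any():
            raise ValueError("report probabilities outside [0, 1]")
        if not np.allclose(self.score_dist.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each score distribution must sum to 1")

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "offsets": OFFSETS.tolist(),
            "report_prob": self.report_prob.tolist(),
            "score_dist": self.score_dist.tolist(),
            "n_source_series": self.n_source_series,
            "course_length_dist": {str(k): v for k, v in self.course_length_dist.items()},
            "bin_halfwidth": self.bin_halfwidth,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "EmpiricalGroupProfile":
        return cls(
            group=data["group"],
            report_prob=np.array(data["report_prob"], dtype=float),
            score_dist=np.array(data["score_dist"], dtype=float),
            n_source_series=int(data["n_source_series"]),
            course_length_dist={int(k): float(v)
                                for k, v in data["course_length_dist"].items()},
            bin_halfwidth=int(data.get("bin_halfwidth", 3)),
        )


# ---------------------------------------------------------------------------
# layer (a): raw cohort generation
# ---------------------------------------------------------------------------

def _elevation(offset: int, peak_day: int, prodrome_days: int,
               recovery_days: int) -> float:
    """Triangular prodromal ramp: 0 before -prodrome_days, 1 at peak_day."""
    if -prodrome_days <= offset <= peak_day:
        return (offset + prodrome_days) / (prodrome_days + peak_day)
    if peak_day < offset <= peak_day + recovery_days:
        return 1.0 - (offset - peak_day) / recovery_days
    return 0.0


def _saba_shape(offset: int, prodrome_days: int, recovery_days: int) -> float:
    """Reliever-usage ramp peaking exactly at onset (offset 0)."""
    if -prodrome_days <= offset <= 0:
        return (offset + prodrome_days) / prodrome_days
    if 0 < offset <= recovery_days:
        return 1.0 - offset / recovery_days
    return 0.0


def _sample_categorical(rng: np.random.Generator, values: Sequence,
                        probs: Sequence[float]):
    return values[int(rng.choice(len(values), p=np.asarray(probs, dtype=float)))]


def generate_cohort(config: CohortConfig) -> dict[str, pd.DataFrame]:
    """Generate a synthetic cohort of diary tables with ground truth.

    Returns a dict of DataFrames: ``symptoms``, ``medications``,
    ``profiles``, ``truth_users`` (intended archetype per user) and
    ``truth_events`` (intended onset dates and per-event signal scale).
    Fully deterministic given ``config.seed`` (per-user substreams).
    """
    config.validate()
    classes = ("infrequent", "intermediate", "frequent")
    mix = [config.engagement_mix[c] for c in classes]
    start = pd.Timestamp(config.start_date)
    root = np.random.SeedSequence(config.seed)
    user_seeds = root.spawn(max(config.n_users, 1))

    event_counts = sorted(config.exacerbations_per_user)
    event_probs = [config.exacerbations_per_user[k] for k in event_counts]

    sym_rows: list[tuple] = []
    med_rows: list[tuple] = []
    prof_rows: list[dict] = []
    truth_user_rows: list[dict] = []
    truth_event_rows: list[dict] = []

    for i in range(config.n_users):
        rng = np.random.default_rng(user_seeds[i])
        user_id = f"u{i:04d}"
        cls = _sample_categorical(rng, classes, mix)
        lo, hi = config.report_prob_bands[cls]
        p_base = float(rng.uniform(lo, hi))
        transitions = (cls != "frequent"
                       and rng.random() < config.transition_prob.get(cls, 0.0))
        if transitions:
            nlo, nhi = config.near_onset_bands[cls]
            p_near = float(rng.uniform(nlo, nhi))
        else:
            p_near = p_base

        n_events = int(_sample_categorical(rng, event_counts, event_probs))
        onsets = []
        day = 100
        for _ in range(n_events):
            day += int(rng.integers(0, 30))
            onsets.append(day)
            day += config.event_spacing_days
        horizon = onsets[-1] + OFFSET_MAX + 10

        # per-event signal scale: first in-app event carries weaker signal
        scales = [config.first_event_shift_scale] + [1.0] * (n_events - 1)

        base = np.array(list(config.baseline_score_dist) + [0.0])
        elevated = np.array(config.elevated_score_dist, dtype=float)
        peak = config.saba_lead_days

        for t in range(horizon + 1):
            rel = [(t - o, s) for o, s in zip(onsets, scales)]
            elev = max(
                (s * _elevation(d, peak, config.prodrome_days,
                                config.recovery_days) for d, s in rel),
                default=0.0,
            )
            near = any(-config.transition_window_days <= d <= -1 for d, _ in rel)
            p_report = p_near if (transitions and near) else p_base
            if rng.random() < p_report:
                w = min(1.0, elev * config.prodrome_shift)
                dist = (1.0 - w) * base + w * elevated
                score = int(_sample_categorical(rng, SCORE_VALUES, dist))
                sym_rows.append((user_id, start + pd.Timedelta(days=t), score))
            # reliever usage only emitted inside event windows
            in_window = any(OFFSET_MIN <= d <= OFFSET_MAX for d, _ in rel)
            if in_window:
                shape = max(
                    (s * _saba_shape(d, config.prodrome_days, config.recovery_days)
                     for d, s in rel),
                    default=0.0,
                )
                lam = config.saba_base_rate + config.saba_peak_rate * shape
                count = int(rng.poisson(lam))
                if count > 0:
                    date = start + pd.Timedelta(days=t)
                    med_rows.append((user_id, "saba", date, date, None, count))

        for j, (onset_day, scale) in enumerate(zip(onsets, scales)):
            onset = start + pd.Timedelta(days=onset_day)
            length = int(rng.integers(config.course_length_range[0],
                                      config.course_length_range[1] + 1))
            if rng.random() < config.retrospective_prob.get(cls, 0.0):
                entry = onset + pd.Timedelta(days=int(rng.integers(11, 31)))
            else:
                entry = onset + pd.Timedelta(days=int(rng.integers(0, 4)))
            med_rows.append((user_id, "rescue_pack", onset, entry, length, None))
            truth_event_rows.append(
                {"user_id": user_id, "onset_date": onset, "event_index": j,
                 "signal_scale": scale, "course_length": length}
            )

        history = int(rng.poisson({"infrequent": 0.6, "intermediate": 1.0,
                                   "frequent": 1.6}[cls]))
        prof_rows.append(
            {
                "user_id": user_id,
                "age": int(np.clip(rng.normal(68.8, 8.3), 40, 95)),
                "sex": "male" if rng.random() < 0.607 else "female",
                "cat_score": int(np.clip(rng.normal(18, 8), 0, 40)),
                "mmrc": int(rng.integers(0, 5)),
                "moderate_exacerbations_last_year": history,
                "hospitalisations_last_year": int(rng.random() < 0.2),
            }
        )
        truth_user_rows.append(
            {"user_id": user_id, "class_intent": cls, "p_base": p_base,
             "p_near": p_near, "transition_intent": transitions}
        )

    symptoms = pd.DataFrame(sym_rows, columns=["user_id", "date", "score"])
    medications = pd.DataFrame(
        med_rows,
        columns=["user_id", "drug_class", "use_date", "entry_date",
                 "course_length", "daily_count"],
    )
    if not medications.empty:
        medications["course_length"] = medications["course_length"].astype("Int64")
        medications["daily_count"] = medications["daily_count"].astype("Int64")
    return {
        "symptoms": symptoms,
        "medications": medications,
        "profiles": pd.DataFrame(prof_rows),
        "truth_users": pd.DataFrame(truth_user_rows),
        "truth_events": pd.DataFrame(truth_event_rows),
    }


# ---------------------------------------------------------------------------
# layer (b): empirical group profiles and series simulation
# ---------------------------------------------------------------------------

def series_from_events(
    events: pd.DataFrame,
    symptoms: pd.DataFrame,
    groups: Sequence[str],
) -> list[SimulatedSeries]:
    """Extract exacerbation-aligned series (-70..+70) for each event.

    ``groups`` assigns one label per event row (e.g. the five model groups).
    """
    if len(groups) != len(events):
        raise ValueError("one group label per event required")
    by_user = dict(tuple(symptoms.groupby("user_id", sort=False)))
    out = []
    for idx, (ev, group) in enumerate(zip(events.itertuples(index=False), groups)):
        user_rows = by_user.get(ev.user_id)
        records: dict[int, int] = {}
        if user_rows is not None:
            offs = (user_rows["date"] - ev.onset_date).dt.days.to_numpy()
            keep = (offs >= OFFSET_MIN) & (offs <= OFFSET_MAX)
            records = {int(d): int(s) for d, s in
                       zip(offs[keep], user_rows["score"].to_numpy()[keep])}
        out.append(
            SimulatedSeries(
                series_id=f"src-{idx:05d}",
                group=str(group),
                records=records,
                course_length=int(ev.course_length),
            )
        )
    return out


def fit_group_profile(
    series: Sequence[SimulatedSeries],
    *,
    group: Optional[str] = None,
    bin_halfwidth: int = 3,
) -> EmpiricalGroupProfile:
    """Fit an :class:`EmpiricalGroupProfile` from exacerbation-aligned series.

    ``report_prob(d)`` is the exact share of series reporting at offset
    ``d``.  Score distributions are smoothed by pooling raw score counts
    over offsets ``d - bin_halfwidth .. d + bin_halfwidth`` before
    normalising; offsets whose bin is empty fall back to the pooled global
    distribution (uniform if no scores at all).
    """
    if len(series) == 0:
        raise ValueError("fit_group_profile requires at least one series")
    group = group if group is not None else series[0].group
    counts = np.zeros((N_OFFSETS, 4), dtype=float)
    reports = np.zeros(N_OFFSETS, dtype=float)
    course_counts: dict[int, int] = {}
    for s in series:
        for d, score in s.records.items():
            i = d - OFFSET_MIN
            reports[i] += 1
            counts[i, int(score) - 1] += 1
        course_counts[s.course_length] = course_counts.get(s.course_length, 0) + 1

    report_prob = reports / len(series)
    kernel = np.ones(2 * bin_halfwidth + 1)
    binned = np.vstack(
        [np.convolve(counts[:, k], kernel, mode="same") for k in range(4)]
    ).T
    totals = binned.sum(axis=1)
    global_counts = counts.sum(axis=0)
    if global_counts.sum() > 0:
        fallback = global_counts / global_counts.sum()
    else:
        fallback = np.full(4, 0.25)
    score_dist = np.empty_like(binned)
    for i in range(N_OFFSETS):
        if totals[i] > 0:
            score_dist[i] = binned[i] / totals[i]
        else:
            score_dist[i] = fallback

    n = len(series)
    course_dist = {k: v / n for k, v in sorted(course_counts.items())}
    return EmpiricalGroupProfile(
        group=group,
        report_prob=report_prob,
        score_dist=score_dist,
        n_source_series=n,
        course_length_dist=course_dist,
        bin_halfwidth=bin_halfwidth,
    )


def simulate_exacerbation_series(
    profile: EmpiricalGroupProfile,
    n: int,
    seed: int,
) -> list[SimulatedSeries]:
    """Sample ``n`` complete series directly from the empirical distributions.

    For each series and offset ``d`` a report occurs with probability
    ``report_prob(d)`` and its score is drawn from ``score_dist(d)``.
    Course lengths are drawn from the profile's fitted distribution.  One
    root seed with per-series substreams makes the output independent of
    iteration order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    cdf = np.cumsum(profile.score_dist, axis=1)
    lengths = sorted(profile.course_length_dist)
    length_probs = np.array([profile.course_length_dist[k] for k in lengths])
    length_probs = length_probs / length_probs.sum()
    out = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        reported = rng.random(N_OFFSETS) < profile.report_prob
        u = rng.random(N_OFFSETS)
        scores = 1 + (u[:, None] > cdf).sum(axis=1)
        course = int(_sample_categorical(rng, lengths, length_probs))
        records = {int(OFFSETS[j]): int(scores[j])
                   for j in range(N_OFFSETS) if reported[j]}
        out.append(
            SimulatedSeries(
                series_id=f"{profile.group}-{i:05d}",
                group=profile.group,
                records=records,
                course_length=course,
            )
        )
    return out


def series_to_frame(series: Iterable[SimulatedSeries]) -> pd.DataFrame:
    """Flatten series into a tidy frame, one row per registered score."""
    rows = [
        (s.series_id, s.group, s.course_length, d, score)
        for s in series
        for d, score in sorted(s.records.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["series_id", "group", "course_length", "day_offset", "score"],
    )
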