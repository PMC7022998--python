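"""Training-load, recovery and performance metrics for athlete monitoring.

This module turns raw monitoring streams (training log, wellness
questionnaire, mood-state profile, competition results) into the weekly
quantities the geometric adaptation model consumes:

* internal load per session (session-RPE = CR-10 rating x duration),
* Foster's weekly training monotony and strain,
* the acute:chronic workload ratio (ACWR) on weekly load sums,
* performance as percentage of personal best time (%PBT),
* weekly aggregation, max-normalisation, +/-1 binarisation of %PBT,
* competition-style quartile banding, and
* the compliance/inclusion prerequisites filter.

Undefined values (a constant training week has no monotony; the ACWR needs
four weeks of history) are represented as ``math.nan`` / ``None`` rather than
raised, so a season with gaps flows through aggregation unharmed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Metric pairs (x, y) for the five analysed input combinations.
#: Keys are WeeklyMetrics attribute names, before normalisation.
COMBINATIONS: dict[int, tuple[str, str]] = {
    1: ("mean_distance", "mean_session_rpe"),
    2: ("mean_session_rpe", "mean_recovery"),
    3: ("strain", "mean_recovery"),
    4: ("monotony", "mean_recovery"),
    5: ("mean_distance", "acwr"),
}

LIKERT_ITEMS = (
    "sleep_quality",
    "sleep_quantity",
    "soreness",
    "enjoyment",
    "stress",
    "global_recovery",
)

POMS_DIMENSIONS = ("anger", "confusion", "depression", "fatigue", "tension", "vigour")


def _is_missing(v: float | None) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingSession:
    """One recorded training session.

    ``rpe`` is on the modified Borg CR-10 scale (0-10, half steps allowed);
    ``duration`` in minutes, ``distance`` in metres (0 for dry-land work).
    """

    date: date
    rpe: float
    duration: float
    distance: float = 0.0
    sport: str = "swimming"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rpe <= 10.0:
            raise ValueError(f"rpe must be in [0, 10], got {self.rpe}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.distance < 0:
            raise ValueError(f"distance must be >= 0, got {self.distance}")


@dataclass(frozen=True)
class WellbeingEntry:
    """Wellness questionnaire entry; every item on a 7-point Likert scale."""

    date: date
    sleep_quality: int
    sleep_quantity: int
    soreness: int
    enjoyment: int
    stress: int
    global_recovery: int

    def __post_init__(self) -> None:
        for item in LIKERT_ITEMS:
            v = getattr(self, item)
            if v not in range(1, 8):
                raise ValueError(f"{item} must be an integer in 1..7, got {v}")

    def composite_recovery(self) -> float:
        """Mean of the five wellness components (alternative recovery input)."""
        return float(
            np.mean([getattr(self, i) for i in LIKERT_ITEMS if i != "global_recovery"])
        )


@dataclass(frozen=True)
class PomsEntry:
    """Mood-state profile entry: six non-negative dimension scores."""

    date: date
    anger: float
    confusion: float
    depression: float
    fatigue: float
    tension: float
    vigour: float

    def __post_init__(self) -> None:
        for dim in POMS_DIMENSIONS:
            if getattr(self, dim) < 0:
                raise ValueError(f"{dim} must be >= 0")


@dataclass(frozen=True)
class PerformanceRecord:
    """A competition result in the athlete's best discipline.

    ``previous_pb_s`` is the personal best at study start and stays fixed for
    the whole season, so every result is scored against the same reference.
    """

    date: date
    discipline: str
    time_s: float
    previous_pb_s: float

    def __post_init__(self) -> None:
        if self.time_s <= 0:
            raise ValueError("time_s must be positive")
        if self.previous_pb_s <= 0:
            raise ValueError("previous_pb_s must be positive")


@dataclass
class AthleteSeries:
    """All monitoring streams of one athlete on a common weekly calendar.

    ``study_start`` must be a Monday; week ``w`` covers days
    ``study_start + 7*(w-1) .. +6``, ``w = 1..n_weeks``.
    """

    athlete_id: str
    study_start: date
    n_weeks: int
    sessions: list[TrainingSession] = field(default_factory=list)
    wellbeing: list[WellbeingEntry] = field(default_factory=list)
    poms: list[PomsEntry] = field(default_factory=list)
    performances: list[PerformanceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.study_start.weekday() != 0:
            raise ValueError("study_start must be a Monday")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        end = self.study_start + timedelta(weeks=self.n_weeks)
        for stream in (self.sessions, self.wellbeing, self.poms, self.performances):
            for entry in stream:
                if not (self.study_start <= entry.date < end):
                    raise ValueError(
                        f"{self.athlete_id}: entry dated {entry.date} outside the "
                        f"study window [{self.study_start}, {end})"
                    )

    def week_of(self, d: date) -> int:
        """1-based study week containing calendar date ``d``."""
        return (d - self.study_start).days // 7 + 1


@dataclass
class WeeklyMetrics:
    """Derived weekly values; ``nan``/``None`` marks an undefined quantity.

    ``mean_distance`` and ``mean_session_rpe`` are mean daily values over the
    seven days of the week (weekly total / 7), so rest days count as zeros;
    only the shape matters downstream because every series is later divided
    by its own maximum.
    """

    week: int
    mean_distance: float = 0.0
    mean_session_rpe: float = 0.0
    monotony: float = math.nan
    strain: float = math.nan
    acwr: float = math.nan
    mean_recovery: float = math.nan
    tmd: float = math.nan
    best_pbt: float | None = None


@dataclass(frozen=True)
class WeeklyTriplet:
    """One week's model input: normalised (x, y) plus the raw %PBT outcome.

    ``label`` is the binary perceptron value: +1 adaptation (%PBT > 100),
    -1 maladaptation; ``None`` when the week had no competition.
    """

    week: int
    x: float
    y: float
    z_pct: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValueError("triplet coordinates must lie in the unit square")
        if (self.z_pct is None) != (self.label is None):
            raise ValueError("label must be present exactly when z_pct is")


@dataclass(frozen=True)
class PrereqDecision:
    include: bool
    failed: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------


def session_rpe(rpe: float, duration: float) -> float:
    """Internal session load in arbitrary units: CR-10 rating x minutes."""
    if not 0.0 <= rpe <= 10.0:
        raise ValueError(f"rpe must be in [0, 10], got {rpe}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return rpe * duration


def training_monotony(daily_loads: Sequence[float], *, ddof: int = 1) -> float:
    """Weekly monotony: mean daily load / SD of daily load (7 values).

    Sample SD (``ddof=1``) by default; a constant week (zero SD) has no
    defined monotony and returns ``nan``.
    """
    loads = np.asarray(daily_loads, dtype=float)
    if loads.shape != (7,):
        raise ValueError("monotony needs exactly 7 daily load totals")
    sd = loads.std(ddof=ddof)
    if sd == 0.0:
        return math.nan
    return float(loads.mean() / sd)


def training_strain(weekly_total_load: float, monotony: float) -> float:
    """Weekly strain: total weekly load x monotony (undefined propagates)."""
    if _is_missing(monotony):
        return math.nan
    return weekly_total_load * monotony


def acwr(
    weekly_loads: Sequence[float], week: int, *, exclude_current: bool = False
) -> float:
    """Acute:chronic workload ratio at 1-based ``week``.

    Acute load is the week's total; chronic load is the rolling mean of the
    four weekly totals ending at the current week (``exclude_current=True``
    instead averages the three preceding weeks only). Undefined (``nan``)
    before week 4 or when the chronic load is zero.
    """
    loads = np.asarray(weekly_loads, dtype=float)
    if week < 4 or week > len(loads):
        return math.nan
    window = loads[week - 4 : week - 1] if exclude_current else loads[week - 4 : week]
    chronic = window.mean()
    if chronic <= 0:
        return math.nan
    return float(loads[week - 1] / chronic)


def percent_pbt(previous_pb_s: float, time_s: float) -> float:
    """Performance as percentage of personal best: (pb / time)^2 x 100."""
    if previous_pb_s <= 0 or time_s <= 0:
        raise ValueError("times must be positive")
    return (previous_pb_s / time_s) ** 2 * 100.0


def total_mood_disturbance(poms: PomsEntry) -> float:
    """TMD: sum of the five negative mood dimensions minus vigour.

    No +100 offset is applied; an offset is a monotone shift and irrelevant
    to the rank-based statistics downstream.
    """
    return (
        poms.anger + poms.confusion + poms.depression + poms.fatigue + poms.tension
    ) - poms.vigour


def binarize_pbt(z_pct: float | None) -> int | None:
    """Binary perceptron label: +1 if %PBT strictly exceeds 100, else -1.

    Exactly 100 counts as maladaptation: improvement means beating, not
    merely matching, the personal best.
    """
    if _is_missing(z_pct):
        return None
    if z_pct <= 0:
        raise ValueError("%PBT must be positive")
    return 1 if z_pct > 100.0 else -1


def normalize_series(values: Sequence[float]) -> np.ndarray:
    """Divide a series by its maximum so the largest value is exactly 1.

    ``nan`` entries pass through; the maximum is taken over defined values
    and must be positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        raise ValueError("cannot normalize an empty/all-missing series")
    m = np.nanmax(arr)
    if m <= 0:
        raise ValueError("cannot normalize a series with non-positive maximum")
    return arr / m


def assign_quartiles(values: Sequence[float]) -> np.ndarray:
    """Competition-style quartile band (1..4) for each value.

    Uses ascending minimum ranks (ties share the lowest rank) and the
    banding ``floor((r - 1) * 4 / n) + 1``, so with ties a whole tied group
    lands in the band of its best-placed member.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 4:
        raise ValueError("quartile banding needs at least 4 values")
    r = rankdata(arr, method="min")
    return ((r - 1) * 4 // n + 1).astype(int)


# ---------------------------------------------------------------------------
# Weekly aggregation
# ---------------------------------------------------------------------------


def weekly_aggregate(
    series: AthleteSeries,
    *,
    recovery_item: str = "global",
    monotony_ddof: int = 1,
    acwr_exclude_current: bool = False,
) -> list[WeeklyMetrics]:
    """Collapse an athlete's season into one :class:`WeeklyMetrics` per week.

    ``recovery_item`` selects the recovery input: ``"global"`` uses the single
    global-recovery Likert item, ``"composite"`` the mean of the five wellness
    components. Weeks without the relevant entries yield missing values; the
    best weekly %PBT is the maximum over that week's competitions.
    """
    if recovery_item not in ("global", "composite"):
        raise ValueError("recovery_item must be 'global' or 'composite'")

    W = series.n_weeks
    daily_loads = np.zeros((W, 7))
    daily_dist = np.zeros((W, 7))
    for s in series.sessions:
        w = series.week_of(s.date)
        d = (s.date - series.study_start).days % 7
        daily_loads[w - 1, d] += session_rpe(s.rpe, s.duration)
        daily_dist[w - 1, d] += s.distance

    weekly_load_sums = daily_loads.sum(axis=1)

    recovery_by_week: dict[int, list[float]] = {}
    for e in series.wellbeing:
        v = e.global_recovery if recovery_item == "global" else e.composite_recovery()
        recovery_by_week.setdefault(series.week_of(e.date), []).append(float(v))

    tmd_by_week: dict[int, list[float]] = {}
    for p in series.poms:
        tmd_by_week.setdefault(series.week_of(p.date), []).append(
            total_mood_disturbance(p)
        )

    pbt_by_week: dict[int, list[float]] = {}
    for perf in series.performances:
        pbt_by_week.setdefault(series.week_of(perf.date), []).append(
            percent_pbt(perf.previous_pb_s, perf.time_s)
        )

    out: list[WeeklyMetrics] = []
    for w in range(1, W + 1):
        mono = training_monotony(daily_loads[w - 1], ddof=monotony_ddof)
        rec = recovery_by_week.get(w)
        tmd = tmd_by_week.get(w)
        pbts = pbt_by_week.get(w)
        out.append(
            WeeklyMetrics(
                week=w,
                mean_distance=float(daily_dist[w - 1].mean()),
                mean_session_rpe=float(daily_loads[w - 1].mean()),
                monotony=mono,
                strain=training_strain(weekly_load_sums[w - 1], mono),
                acwr=acwr(weekly_load_sums, w, exclude_current=acwr_exclude_current),
                mean_recovery=float(np.mean(rec)) if rec else math.nan,
                tmd=float(np.mean(tmd)) if tmd else math.nan,
                best_pbt=max(pbts) if pbts else None,
            )
        )
    return out


def raw_combination(
    metrics: Sequence[WeeklyMetrics], combo: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw (un-normalised) x, y, z series for one input combination.

    Returns ``(weeks, x, y, z)`` arrays restricted to weeks where both x and
    y are defined; ``z`` is the best weekly %PBT with ``nan`` for weeks
    without competition. Dropped weeks are logged.
    """
    if combo not in COMBINATIONS:
        raise ValueError(f"unknown combination id {combo}; expected 1..5")
    xf, yf = COMBINATIONS[combo]
    weeks, xs, ys, zs = [], [], [], []
    for m in metrics:
        x = getattr(m, xf)
        y = getattr(m, yf)
        if _is_missing(x) or _is_missing(y):
            logger.warning(
                "combination %d: dropping week %d (undefined %s)",
                combo,
                m.week,
                xf if _is_missing(x) else yf,
            )
            continue
        weeks.append(m.week)
        xs.append(float(x))
        ys.append(float(y))
        zs.append(math.nan if m.best_pbt is None else float(m.best_pbt))
    return (
        np.asarray(weeks, dtype=int),
        np.asarray(xs, dtype=float),
        np.asarray(ys, dtype=float),
        np.asarray(zs, dtype=float),
    )


def triplets_from_raw(
    weeks: np.ndarray, x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> list[WeeklyTriplet]:
    """Normalise raw x/y series and binarise z into weekly triplets."""
    xn = normalize_series(x)
    yn = normalize_series(y)
    out = []
    for i, w in enumerate(weeks):
        z_pct = None if math.isnan(z[i]) else float(z[i])
        out.append(
            WeeklyTriplet(
                week=int(w),
                x=float(xn[i]),
                y=float(yn[i]),
                z_pct=z_pct,
                label=binarize_pbt(z_pct),
            )
        )
    return out


def build_combination(
    metrics: Sequence[WeeklyMetrics], combo: int
) -> list[WeeklyTriplet]:
    """Weekly triplets for one combination: normalised x, y plus %PBT label."""
    return triplets_from_raw(*raw_combination(metrics, combo))


# ---------------------------------------------------------------------------
# Inclusion prerequisites
# ---------------------------------------------------------------------------


def apply_prerequisites(
    series: AthleteSeries,
    attendance: float,
    response_rates: dict[str, float],
    *,
    metrics: Sequence[WeeklyMetrics] | None = None,
) -> PrereqDecision:
    """Decide whether an athlete enters the modelling, with reasons.

    All four must hold: every questionnaire response rate strictly above 80%;
    strictly more than 75% of training sessions recorded; at least one %PBT
    above and one below 100%; and defined training + recovery data for every
    week that has a %PBT value.
    """
    for name, rate in response_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"response rate {name} outside [0, 1]")
    if not 0.0 <= attendance <= 1.0:
        raise ValueError("attendance outside [0, 1]")

    failed: list[str] = []
    low = [n for n, r in response_rates.items() if r <= 0.80]
    if low:
        failed.append(f"questionnaire response rate <= 80%: {', '.join(sorted(low))}")
    if attendance <= 0.75:
        failed.append("recorded-session fraction <= 75%")

    pbts = [percent_pbt(p.previous_pb_s, p.time_s) for p in series.performances]
    if not any(v > 100.0 for v in pbts):
        failed.append("no %PBT value over 100%")
    if not any(v < 100.0 for v in pbts):
        failed.append("no %PBT value under 100%")

    if metrics is None:
        metrics = weekly_aggregate(series)
    for m in metrics:
        if m.best_pbt is not None and (
            m.mean_session_rpe == 0.0 or _is_missing(m.mean_recovery)
        ):
            failed.append(f"incomplete (x, y) data in competition week {m.week}")

    return PrereqDecision(include=not failed, failed=tuple(failed))
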