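from datetime import date, timedelta

import pytest
from hypothesis import HealthCheck, settings

from adaptgeom import (
    AthleteSeries,
    LabelledPoint,
    PerformanceRecord,
    TrainingSession,
    WellbeingEntry,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

START = date(2013, 9, 30)  # a Monday


def make_series(
    weekly_specs,
    athlete_id: str = "T1",
    n_weeks: int | None = None,
) -> AthleteSeries:
    """Hand-built season from per-week specs.

    Each spec is a dict with optional keys: ``sessions`` (list of
    (rpe, duration, distance) placed on consecutive days), ``recovery``
    (list of global-recovery Likert values, one entry per value), ``pbt``
    (list of %PBT percentages realised as competition times against a 60 s
    personal best).
    """
    sessions, wellbeing, performances = [], [], []
    for w, spec in enumerate(weekly_specs, start=1):
        base = START + timedelta(weeks=w - 1)
        for d, (rpe, dur, dist) in enumerate(spec.get("sessions", [])):
            sessions.append(
                TrainingSession(base + timedelta(days=d % 7), rpe, dur, dist)
            )
        for i, rec in enumerate(spec.get("recovery", [])):
            wellbeing.append(
                WellbeingEntry(
                    base + timedelta(days=(1, 4)[i % 2]),
                    sleep_quality=4,
                    sleep_quantity=4,
                    soreness=4,
                    enjoyment=4,
                    stress=4,
                    global_recovery=rec,
                )
            )
        for i, pct in enumerate(spec.get("pbt", [])):
            performances.append(
                PerformanceRecord(
                    base + timedelta(days=min(5 + i, 6)),
                    "100 freestyle",
                    time_s=60.0 / (pct / 100.0) ** 0.5,
                    previous_pb_s=60.0,
                )
            )
    return AthleteSeries(
        athlete_id=athlete_id,
        study_start=START,
        n_weeks=n_weeks or len(weekly_specs),
        sessions=sessions,
        wellbeing=wellbeing,
        performances=performances,
    )


@pytest.fixture
def separable_points() -> list[LabelledPoint]:
    """Eight points, +1 strictly left of x=0.4, -1 strictly right of 0.6."""
    plus = [(0.1, 0.2), (0.2, 0.7), (0.3, 0.4), (0.15, 0.55)]
    minus = [(0.7, 0.3), (0.8, 0.8), (0.9, 0.5), (0.75, 0.6)]
    return [
        LabelledPoint(week=i + 1, p=p, label=1) for i, p in enumerate(plus)
    ] + [
        LabelledPoint(week=i + 5, p=p, label=-1) for i, p in enumerate(minus)
    ]


@pytest.fixture
def mirror_points() -> list[LabelledPoint]:
    """Left/right mirror-symmetric classes about the vertical midline."""
    plus = [(0.1, 0.1), (0.3, 0.5), (0.1, 0.9), (0.25, 0.3)]
    minus = [(1 - x, y) for x, y in plus]
    return [
        LabelledPoint(week=i + 1, p=p, label=1) for i, p in enumerate(plus)
    ] + [
        LabelledPoint(week=i + 5, p=p, label=-1) for i, p in enumerate(minus)
    ]
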