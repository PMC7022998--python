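"""CSV interchange for the four monitoring streams.

One file per stream, all athletes together, keyed by ``athlete_id``:

* ``sessions.csv``: athlete_id,date,sport,rpe,duration_min,distance_m
* ``wellbeing.csv``: athlete_id,date,<six 7-point Likert items>
* ``poms.csv``: athlete_id,date,<six mood dimensions>
* ``performances.csv``: athlete_id,date,discipline,time_s,previous_pb_s

Dates are ISO-8601. Malformed rows are rejected with the offending file line
number; writing then re-reading a cohort is lossless.
"""

from __future__ import annotations

from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

from .load_metrics import (
    LIKERT_ITEMS,
    POMS_DIMENSIONS,
    AthleteSeries,
    PerformanceRecord,
    PomsEntry,
    TrainingSession,
    WellbeingEntry,
)

SESSION_COLUMNS = ["athlete_id", "date", "sport", "rpe", "duration_min", "distance_m"]
WELLBEING_COLUMNS = ["athlete_id", "date", *LIKERT_ITEMS]
POMS_COLUMNS = ["athlete_id", "date", *POMS_DIMENSIONS]
PERFORMANCE_COLUMNS = ["athlete_id", "date", "discipline", "time_s", "previous_pb_s"]


def _parse_date(value: str) -> date:
    return datetime.strptime(str(value), "%Y-%m-%d").date()


def _read_validated(
    path: str | Path,
    columns: list[str],
    row_parser: Callable[[pd.Series], object],
) -> dict[str, list]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"athlete_id": str})
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list] = {}
    for i, row in df.iterrows():
        lineno = i + 2  # 1-based, after the header line
        try:
            entry = row_parser(row)
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        out.setdefault(str(row["athlete_id"]), []).append(entry)
    return out


def read_sessions(path: str | Path) -> dict[str, list[TrainingSession]]:
    return _read_validated(
        path,
        SESSION_COLUMNS,
        lambda r: TrainingSession(
            date=_parse_date(r["date"]),
            rpe=float(r["rpe"]),
            duration=float(r["duration_min"]),
            distance=float(r["distance_m"]),
            sport=str(r["sport"]),
        ),
    )


def read_wellbeing(path: str | Path) -> dict[str, list[WellbeingEntry]]:
    return _read_validated(
        path,
        WELLBEING_COLUMNS,
        lambda r: WellbeingEntry(
            date=_parse_date(r["date"]),
            **{item: int(r[item]) for item in LIKERT_ITEMS},
        ),
    )


def read_poms(path: str | Path) -> dict[str, list[PomsEntry]]:
    return _read_validated(
        path,
        POMS_COLUMNS,
        lambda r: PomsEntry(
            date=_parse_date(r["date"]),
            **{dim: float(r[dim]) for dim in POMS_DIMENSIONS},
        ),
    )


def read_performances(path: str | Path) -> dict[str, list[PerformanceRecord]]:
    return _read_validated(
        path,
        PERFORMANCE_COLUMNS,
        lambda r: PerformanceRecord(
            date=_parse_date(r["date"]),
            discipline=str(r["discipline"]),
            time_s=float(r["time_s"]),
            previous_pb_s=float(r["previous_pb_s"]),
        ),
    )


def load_cohort(
    directory: str | Path, study_start: date, n_weeks: int
) -> dict[str, AthleteSeries]:
    """Assemble one :class:`AthleteSeries` per athlete from the four CSVs."""
    directory = Path(directory)
    sessions = read_sessions(directory / "sessions.csv")
    wellbeing = read_wellbeing(directory / "wellbeing.csv")
    poms = read_poms(directory / "poms.csv")
    performances = read_performances(directory / "performances.csv")
    ids = sorted(set(sessions) | set(wellbeing) | set(poms) | set(performances))
    return {
        aid: AthleteSeries(
            athlete_id=aid,
            study_start=study_start,
            n_weeks=n_weeks,
            sessions=sessions.get(aid, []),
            wellbeing=wellbeing.get(aid, []),
            poms=poms.get(aid, []),
            performances=performances.get(aid, []),
        )
        for aid in ids
    }


def write_cohort(cohort: Iterable[AthleteSeries], directory: str | Path) -> None:
    """Write the four standard CSVs for a collection of athletes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    srows, wrows, prows, frows = [], [], [], []
    for a in cohort:
        for s in sorted(a.sessions, key=lambda e: e.date):
            srows.append(
                [a.athlete_id, s.date.isoformat(), s.sport, s.rpe, s.duration, s.distance]
            )
        for w in sorted(a.wellbeing, key=lambda e: e.date):
            wrows.append(
                [a.athlete_id, w.date.isoformat()]
                + [getattr(w, i) for i in LIKERT_ITEMS]
            )
        for p in sorted(a.poms, key=lambda e: e.date):
            prows.append(
                [a.athlete_id, p.date.isoformat()]
                + [getattr(p, d) for d in POMS_DIMENSIONS]
            )
        for f in sorted(a.performances, key=lambda e: e.date):
            frows.append(
                [a.athlete_id, f.date.isoformat(), f.discipline, f.time_s, f.previous_pb_s]
            )
    pd.DataFrame(srows, columns=SESSION_COLUMNS).to_csv(
        directory / "sessions.csv", index=False
    )
    pd.DataFrame(wrows, columns=WELLBEING_COLUMNS).to_csv(
        directory / "wellbeing.csv", index=False
    )
    pd.DataFrame(prows, columns=POMS_COLUMNS).to_csv(
        directory / "poms.csv", index=False
    )
    pd.DataFrame(frows, columns=PERFORMANCE_COLUMNS).to_csv(
        directory / "performances.csv", index=False
    )
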