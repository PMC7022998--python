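"""Synthetic athlete seasons with a known adaptation rule.

No monitoring series were ever published for this kind of study, so the
generator emulates the study conditions end to end: a 26-week season of
swim sessions (lognormal weekly distance split over ~7 sessions, CR-10
ratings coupled to session volume), twice-weekly wellness entries whose
recovery item falls with the week's load, fortnightly mood profiles, and
competitions on a sparse subset of 4-8 weeks. A latent geometric rule on
the *normalised* weekly (x, y) coordinates of a chosen input combination
decides whether each competition beats the personal best (%PBT above or
below 100), optionally corrupted by label-flip noise — so the fitted region
map has a ground truth, with a closed-form adaptation/maladaptation area
ratio, to recover.

Everything is deterministic given the cohort seed; athlete ``i`` draws from
an independent stream derived from ``(seed, i)``.

The module also carries the published characteristics table of the thirteen
swimmers who met the inclusion prerequisites in the original cohort
(sex, age, best discipline, FINA points, best %PBT, weekly mean internal
load and distance, each with its published quartile band) — the one
published dataset against which the quartile banding is exactly
recomputable.
"""

from __future__ import annotations

import io as _stdio
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .load_metrics import (
    AthleteSeries,
    PerformanceRecord,
    PomsEntry,
    PrereqDecision,
    TrainingSession,
    WellbeingEntry,
    apply_prerequisites,
    raw_combination,
    weekly_aggregate,
)
from .io import write_cohort

UNIT_SQUARE = box(0.0, 0.0, 1.0, 1.0)

#: Monday opening the emulated observation window (an autumn macrocycle).
DEFAULT_STUDY_START = date(2013, 9, 30)


# ---------------------------------------------------------------------------
# Ground-truth rules
# ---------------------------------------------------------------------------


def _halfplane_polygon(a: float, b: float, c: float, extent: float = 10.0) -> Polygon:
    """The halfplane a*x + b*y + c >= 0 as a large polygon (for clipping)."""
    norm = math.hypot(a, b)
    if norm == 0:
        raise ValueError("halfplane needs a non-zero normal")
    nx, ny = a / norm, b / norm  # unit normal, pointing into the kept side
    dx, dy = -ny, nx
    px, py = -c / norm * nx, -c / norm * ny  # foot of the normal on the line
    L = extent
    return Polygon(
        [
            (px - L * dx, py - L * dy),
            (px + L * dx, py + L * dy),
            (px + L * dx + L * nx, py + L * dy + L * ny),
            (px - L * dx + L * nx, py - L * dy + L * ny),
        ]
    )


@dataclass(frozen=True)
class GroundTruthRule:
    """Latent adaptation rule on the unit square.

    ``halfplane``: adapt iff a*x + b*y + c > 0 (params a, b, c).
    ``band``: adapt iff |a*x + b*y + c| <= w (params a, b, c, w).
    ``disk``: adapt iff (x, y) within radius r of (cx, cy) (params cx, cy, r).
    """

    kind: str = "halfplane"
    params: tuple[float, ...] = (1.0, -1.0, 0.0)  # default: adapt iff y < x

    def region(self) -> Polygon:
        """Adaptation region clipped to the unit square."""
        if self.kind == "halfplane":
            a, b, c = self.params
            poly = _halfplane_polygon(a, b, c)
        elif self.kind == "band":
            a, b, c, w = self.params
            poly = _halfplane_polygon(a, b, c + w).intersection(
                _halfplane_polygon(-a, -b, w - c)
            )
        elif self.kind == "disk":
            cx, cy, r = self.params
            poly = Point(cx, cy).buffer(r, quad_segs=512)
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        return poly.intersection(UNIT_SQUARE)

    def contains(self, x: float, y: float) -> bool:
        if self.kind == "halfplane":
            a, b, c = self.params
            return a * x + b * y + c > 0
        if self.kind == "band":
            a, b, c, w = self.params
            return abs(a * x + b * y + c) <= w
        if self.kind == "disk":
            cx, cy, r = self.params
            return (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        raise ValueError(f"unknown rule kind {self.kind!r}")

    @property
    def true_area_ratio(self) -> float:
        """Adaptation/maladaptation area ratio of the rule on the unit square."""
        adapt = self.region().area
        malad = 1.0 - adapt
        if malad <= 0:
            return math.inf
        return adapt / malad


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the generator.

    Defaults emulate the monitored season: 26 weeks, ~7 sessions and ~20 km
    in the water per week (the included swimmers' weekly means spanned
    roughly 14-32 km), exertion rising with session volume, recovery falling
    with weekly load, and 4-8 competition weeks per athlete.
    """

    n_athletes: int = 20
    n_weeks: int = 26
    sessions_per_week: float = 7.0
    distance_mean: float = 20_000.0  # metres per week
    distance_sd: float = 5_000.0
    rpe_slope: float = 2.0  # CR-10 points per unit relative session volume
    rpe_noise: float = 0.7
    recovery_slope: float = 1.2  # Likert points lost per SD of weekly load
    recovery_noise: float = 0.8
    competition_weeks: tuple[int, int] = (4, 8)  # inclusive count range
    rule: GroundTruthRule = field(default_factory=GroundTruthRule)
    label_noise: float = 0.0
    combo: int = 1  # combination whose (x, y) the rule is applied to
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 8:
            raise ValueError("n_weeks must be >= 8")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        lo, hi = self.competition_weeks
        if not (1 <= lo <= hi <= self.n_weeks - 3):
            raise ValueError("competition week count range incompatible with season")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _round_half_step(v: float) -> float:
    return round(v * 2.0) / 2.0


def simulate_athlete(config: CohortConfig, index: int) -> AthleteSeries:
    """One athlete's full season; deterministic given (config.seed, index)."""
    rng = np.random.default_rng([config.seed, index])
    start = DEFAULT_STUDY_START
    W = config.n_weeks

    pace = float(np.clip(rng.normal(35.0, 4.0), 25.0, 50.0))  # metres / minute
    pb_s = float(rng.uniform(28.0, 290.0))
    mu, sigma = _lognormal_params(config.distance_mean, config.distance_sd)
    weekly_distance = rng.lognormal(mu, sigma, W)

    sessions: list[TrainingSession] = []
    per_session_ref = config.distance_mean / config.sessions_per_week
    for w in range(W):
        k = int(np.clip(rng.poisson(config.sessions_per_week), 1, 14))
        days = rng.integers(0, 7, size=k)
        split = rng.dirichlet(np.full(k, 4.0)) * weekly_distance[w]
        for d, dist in zip(days, split):
            rel = dist / per_session_ref
            rpe = float(
                np.clip(
                    _round_half_step(3.0 + config.rpe_slope * rel + rng.normal(0, config.rpe_noise)),
                    0.5,
                    10.0,
                )
            )
            sessions.append(
                TrainingSession(
                    date=start + timedelta(days=7 * w + int(d)),
                    rpe=rpe,
                    duration=max(20.0, dist / pace),
                    distance=float(dist),
                    sport="swimming",
                )
            )

    load_z = (weekly_distance - weekly_distance.mean()) / weekly_distance.std(ddof=1)
    wellbeing: list[WellbeingEntry] = []
    for w in range(W):
        for day in (1, 4):  # Tuesday and Friday
            rec = int(
                np.clip(
                    round(4.0 - config.recovery_slope * load_z[w] + rng.normal(0, config.recovery_noise)),
                    1,
                    7,
                )
            )
            items = {
                item: int(np.clip(round(rec + rng.normal(0, 1.0)), 1, 7))
                for item in (
                    "sleep_quality",
                    "sleep_quantity",
                    "soreness",
                    "enjoyment",
                    "stress",
                )
            }
            wellbeing.append(
                WellbeingEntry(
                    date=start + timedelta(days=7 * w + day),
                    global_recovery=rec,
                    **items,
                )
            )

    poms = [
        PomsEntry(
            date=start + timedelta(days=7 * w + 6),
            anger=float(rng.poisson(3)),
            confusion=float(rng.poisson(3)),
            depression=float(rng.poisson(2)),
            fatigue=float(rng.poisson(4)),
            tension=float(rng.poisson(3)),
            vigour=float(rng.poisson(8)),
        )
        for w in range(1, W, 2)
    ]

    # latent rule applies to the normalised combination coordinates
    provisional = AthleteSeries(
        athlete_id=f"S{index:02d}",
        study_start=start,
        n_weeks=W,
        sessions=sessions,
        wellbeing=wellbeing,
        poms=poms,
    )
    metrics = weekly_aggregate(provisional)
    weeks, x_raw, y_raw, _ = raw_combination(metrics, config.combo)
    xn = x_raw / x_raw.max()
    yn = y_raw / y_raw.max()
    coord = {int(w): (float(xn[i]), float(yn[i])) for i, w in enumerate(weeks)}

    lo, hi = config.competition_weeks
    n_comp = int(rng.integers(lo, hi + 1))
    eligible = [w for w in range(4, W + 1) if w in coord]
    comp_weeks = sorted(rng.choice(eligible, size=n_comp, replace=False))

    performances: list[PerformanceRecord] = []
    for w in comp_weeks:
        adapt = config.rule.contains(*coord[int(w)])
        if rng.random() < config.label_noise:
            adapt = not adapt
        margin = float(rng.uniform(0.1, 6.0))
        pct = 100.0 + margin if adapt else 100.0 - margin
        performances.append(
            PerformanceRecord(
                date=start + timedelta(days=7 * (int(w) - 1) + 5),
                discipline="best",
                time_s=pb_s / math.sqrt(pct / 100.0),
                previous_pb_s=pb_s,
            )
        )

    provisional.performances = performances
    return provisional


def simulate_cohort(config: CohortConfig) -> list[AthleteSeries]:
    return [simulate_athlete(config, i) for i in range(config.n_athletes)]


def cohort_prerequisites(series: AthleteSeries) -> PrereqDecision:
    """Prerequisite decision for a simulated athlete (full compliance)."""
    return apply_prerequisites(
        series,
        attendance=1.0,
        response_rates={"wellbeing": 1.0, "poms": 1.0},
    )


def included_athletes(cohort: Sequence[AthleteSeries]) -> list[AthleteSeries]:
    """Athletes passing the inclusion prerequisites, in cohort order.

    Simulated athletes can fail prerequisite (3) when every competition lands
    on one side of the rule, mirroring the exclusion flow of a real cohort.
    """
    return [a for a in cohort if cohort_prerequisites(a).include]


def write_truth(config: CohortConfig, directory: str | Path) -> None:
    doc = {
        "rule": {"kind": config.rule.kind, "params": list(config.rule.params)},
        "true_area_ratio": config.rule.true_area_ratio,
        "config": {
            k: v for k, v in asdict(config).items() if k != "rule"
        },
    }
    Path(directory, "truth.json").write_text(json.dumps(doc, indent=2))


def write_simulated_cohort(config: CohortConfig, directory: str | Path) -> None:
    """The four standard CSVs plus truth.json for a simulated cohort."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_cohort(simulate_cohort(config), directory)
    write_truth(config, directory)


# ---------------------------------------------------------------------------
# Printed characteristics of the thirteen included swimmers
# ---------------------------------------------------------------------------

_SWIMMER_TABLE_CSV = """\
swimmer,sex,age,age_q,discipline,fina,fina_q,best_pbt,best_pbt_q,load,load_q,distance,distance_q
A2,M,18,3,400 freestyle ld,765,4,100.1,1,4258.46,4,30100,4
B5,F,14,1,200 breaststroke ld,633,3,110,4,3144.23,3,18826.92,2
B6,F,15,1,100 freestyle sd,459,1,100.7,1,2775,2,17148,2
B29,F,15,1,50 breaststroke ld,504,1,105.9,3,2377.31,1,15426.92,1
C10,M,19,4,100 medley sd,582,2,103.1,2,2504.81,1,13905.77,1
C13,M,16,2,100 freestyle ld,471,1,103.7,3,3353.08,3,23386.54,3
C14,M,16,2,400 medley ld,445,1,109.2,4,2365.38,1,16350,1
D21,F,15,1,400 freestyle ld,640,3,106.1,4,4417.71,4,27253.33,4
D22,F,15,1,200 breaststroke ld,617,2,102.4,1,2946.4,2,32212.8,4
D35,F,18,3,100 freestyle ld,631,3,100.7,1,2850.38,2,25732.69,3
E24,M,19,4,100 freestyle ld,646,4,104.9,3,2112.5,1,15411.46,1
E27,F,18,3,100 backstroke ld,619,2,102.7,2,4703.27,4,23744.23,3
E28,M,20,4,50 butterfly ld,673,4,103.0,2,3128.46,3,22900,2
"""

#: Columns carrying a printed quartile band, keyed by their value column.
SWIMMER_TABLE_QUARTILE_COLUMNS = {
    "age": "age_q",
    "fina": "fina_q",
    "best_pbt": "best_pbt_q",
    "load": "load_q",
    "distance": "distance_q",
}


def swimmer_characteristics() -> pd.DataFrame:
    """Characteristics of the 13 included swimmers, with printed quartiles.

    Columns: sex, age, best discipline, FINA points, best %PBT, weekly mean
    internal load (AU) and weekly mean distance (m); each value column is
    followed by its published quartile band (``*_q``).
    """
    return pd.read_csv(_stdio.StringIO(_SWIMMER_TABLE_CSV))
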