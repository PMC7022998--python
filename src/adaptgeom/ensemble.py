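"""GAPI, goodness of fit, and the jittered ensemble.

The Geometric Activity Performance Index (GAPI) condenses a fitted region
map into one number: the ratio of the adaptation area to the maladaptation
area of the unit square. Goodness of fit is the percentage of competition
weeks whose point lands in the region matching its label.

Because each athlete contributes only 4-8 labelled weeks, a single fit is
fragile. Jittering superimposes Gaussian noise (SD = ``noise_level`` x the
sample SD of each raw series, 10% by default) on the raw x, y and z series
before normalisation/binarisation, the model is refitted on each of
``replicates`` (default 50) perturbed datasets, and the outputs are combined
by simple averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import (
    NEUTRAL,
    DomainMap,
    LabelledPoint,
    classify_point,
    fit_domain_map,
)
from .load_metrics import (
    AthleteSeries,
    WeeklyTriplet,
    raw_combination,
    triplets_from_raw,
    weekly_aggregate,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JitterConfig:
    """Jittering/ensemble settings: relative noise SD, replicate count, seed."""

    noise_level: float = 0.10
    replicates: int = 50
    seed: int = 0
    multiplicative: bool = False

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class GapiResult:
    """Areas, GAPI, goodness of fit and per-week classifications of one fit."""

    area_adapt: float
    area_malad: float
    area_neutral: float
    gapi: float  # math.inf flags a zero maladaptation area
    goodness_of_fit: int
    per_point: dict[int, tuple[int, int, bool]]  # week -> (label, predicted, correct)
    mce: float = math.nan  # mean cross entropy diagnostic of the hard classifier


@dataclass
class EnsembleResult:
    """50-replicate jittered ensemble with its simple-average summary."""

    members: list[GapiResult]
    mean_gapi: float
    mean_gof: float
    gapi_sd: float
    majority_map: np.ndarray = field(repr=False)
    config: JitterConfig = field(default_factory=JitterConfig)
    degenerate_members: int = 0


# ---------------------------------------------------------------------------
# Areas, GAPI, goodness of fit
# ---------------------------------------------------------------------------


def region_areas(domain_map: DomainMap) -> tuple[float, float, float]:
    """(adaptation, maladaptation, neutral) area fractions by cell counting."""
    labels = domain_map.labels
    total = labels.size
    return (
        float(np.count_nonzero(labels == 1)) / total,
        float(np.count_nonzero(labels == -1)) / total,
        float(np.count_nonzero(labels == NEUTRAL)) / total,
    )


def gapi(areas: tuple[float, float, float]) -> float:
    """GAPI = adaptation area / maladaptation area; inf flags a zero divisor."""
    area_adapt, area_malad = areas[0], areas[1]
    if area_adapt == 0.0 and area_malad == 0.0:
        raise ValueError("degenerate map: both labelled areas are zero")
    if area_malad == 0.0:
        return math.inf
    return area_adapt / area_malad


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def goodness_of_fit(
    domain_map: DomainMap, points: Sequence[LabelledPoint]
) -> tuple[int, dict[int, tuple[int, int, bool]]]:
    """Percent of weeks classified in the region matching their label.

    Returns the integer percentage (half-up rounding, e.g. 7/8 -> 88) and the
    per-week (label, predicted, correct) record; neutral-layer points use the
    nearest labelled region.
    """
    if not points:
        raise ValueError("goodness of fit needs at least one labelled point")
    per_point: dict[int, tuple[int, int, bool]] = {}
    correct = 0
    for p in points:
        pred = classify_point(domain_map, p.p)
        ok = pred == p.label
        correct += ok
        per_point[p.week] = (p.label, pred, ok)
    return _round_half_up(100.0 * correct / len(points)), per_point


def mean_cross_entropy(per_point: dict[int, tuple[int, int, bool]]) -> float:
    """Mean cross entropy of the hard region predictions against the labels.

    Hard +/-1 predictions are read as probabilities clipped away from {0, 1}
    so misclassifications contribute a large, finite penalty.
    """
    eps = 1e-12
    probs = [1.0 - eps if ok else eps for (_, _, ok) in per_point.values()]
    return float(-np.mean(np.log(probs)))


def evaluate_map(
    domain_map: DomainMap, points: Sequence[LabelledPoint]
) -> GapiResult:
    """Areas + GAPI + goodness of fit of one fitted map."""
    areas = region_areas(domain_map)
    gof, per_point = goodness_of_fit(domain_map, points)
    return GapiResult(
        area_adapt=areas[0],
        area_malad=areas[1],
        area_neutral=areas[2],
        gapi=gapi(areas),
        goodness_of_fit=gof,
        per_point=per_point,
        mce=mean_cross_entropy(per_point),
    )


# ---------------------------------------------------------------------------
# Jittering
# ---------------------------------------------------------------------------


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([seed, replicate])


def jitter_series(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    config: JitterConfig,
    replicate: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-perturbed copies of the raw x, y, z series.

    Additive Gaussian noise with SD = ``noise_level`` x the series' sample SD
    (per series), or multiplicative 1 + N(0, noise_level) factors when
    configured. Deterministic given (seed, replicate); missing z entries stay
    missing; x/y are clipped at zero and z at a small positive floor.
    """
    rng = _replicate_rng(config.seed, replicate)
    out = []
    for arr, floor in ((x, 0.0), (y, 0.0), (z, 1e-9)):
        arr = np.asarray(arr, dtype=float)
        if config.noise_level == 0.0:
            out.append(arr.copy())
            continue
        defined = ~np.isnan(arr)
        jittered = arr.copy()
        if config.multiplicative:
            noise = arr[defined] * rng.normal(0.0, config.noise_level, defined.sum())
        else:
            sd = np.std(arr[defined], ddof=1) if defined.sum() > 1 else 0.0
            noise = rng.normal(0.0, config.noise_level * sd, defined.sum())
        jittered[defined] = np.maximum(arr[defined] + noise, floor)
        out.append(jittered)
    return out[0], out[1], out[2]


def labelled_points(triplets: Sequence[WeeklyTriplet]) -> list[LabelledPoint]:
    """Competition weeks of a triplet series as labelled unit-square points."""
    return [
        LabelledPoint(week=t.week, p=(t.x, t.y), label=t.label)
        for t in triplets
        if t.label is not None
    ]


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------


def _fit_member(
    weeks: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    *,
    k_max: int,
    layer_width: float,
    buffer_radius: float,
    grid_resolution: int,
) -> tuple[DomainMap, GapiResult]:
    triplets = triplets_from_raw(weeks, x, y, z)
    points = labelled_points(triplets)
    domain_map = fit_domain_map(
        points,
        k_max=k_max,
        layer_width=layer_width,
        buffer_radius=buffer_radius,
        grid_resolution=grid_resolution,
    )
    return domain_map, evaluate_map(domain_map, points)


def run_ensemble(
    series: AthleteSeries,
    combo: int,
    config: JitterConfig = JitterConfig(),
    *,
    k_max: int = 4,
    layer_width: float = 0.01,
    buffer_radius: float = 0.02,
    grid_resolution: int = 256,
) -> EnsembleResult:
    """Fit the geometric model on ``replicates`` jittered copies and average.

    Members whose jittered labels collapse to a single class (no geometric
    model exists) are counted as degenerate and excluded from the means, with
    a warning. ``mean_gapi``/``mean_gof`` are arithmetic means over the valid
    members; the majority map is the per-cell modal region label.

    With ``noise_level == 0`` every replicate sees identical data, so the
    member is fitted once and replicated.
    """
    metrics = weekly_aggregate(series)
    weeks, x, y, z = raw_combination(metrics, combo)

    members: list[GapiResult] = []
    label_maps: list[np.ndarray] = []
    degenerate = 0

    if config.noise_level == 0.0:
        domain_map, result = _fit_member(
            weeks,
            x,
            y,
            z,
            k_max=k_max,
            layer_width=layer_width,
            buffer_radius=buffer_radius,
            grid_resolution=grid_resolution,
        )
        members = [result] * config.replicates
        label_maps = [domain_map.labels]
    else:
        for r in range(config.replicates):
            xj, yj, zj = jitter_series(x, y, z, config, r)
            try:
                domain_map, result = _fit_member(
                    weeks,
                    xj,
                    yj,
                    zj,
                    k_max=k_max,
                    layer_width=layer_width,
                    buffer_radius=buffer_radius,
                    grid_resolution=grid_resolution,
                )
            except ValueError as exc:
                degenerate += 1
                logger.warning("replicate %d degenerate, excluded: %s", r, exc)
                continue
            members.append(result)
            label_maps.append(domain_map.labels)

    if not members:
        raise ValueError("every ensemble member was degenerate")

    finite = [m.gapi for m in members if math.isfinite(m.gapi)]
    mean_gapi = float(np.mean(finite)) if finite else math.inf
    gapi_sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0

    stack = np.stack(label_maps)  # (members, res, res) over {-1, 0, +1}
    counts = np.stack([(stack == v).sum(axis=0) for v in (-1, NEUTRAL, 1)])
    majority = np.array([-1, NEUTRAL, 1])[counts.argmax(axis=0)]

    return EnsembleResult(
        members=members,
        mean_gapi=mean_gapi,
        mean_gof=float(np.mean([m.goodness_of_fit for m in members])),
        gapi_sd=gapi_sd,
        majority_map=majority,
        config=config,
        degenerate_members=degenerate,
    )
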