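"""Monitoring metrics: session load, monotony, strain, ACWR, %PBT, banding."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adaptgeom import (
    PomsEntry,
    acwr,
    apply_prerequisites,
    assign_quartiles,
    binarize_pbt,
    build_combination,
    normalize_series,
    percent_pbt,
    session_rpe,
    total_mood_disturbance,
    training_monotony,
    training_strain,
    weekly_aggregate,
)
from adaptgeom.cohort import SWIMMER_TABLE_QUARTILE_COLUMNS, swimmer_characteristics
from adaptgeom.load_metrics import raw_combination

from conftest import make_series


@pytest.mark.parametrize(
    "rpe,duration,expected",
    [(7, 60, 420.0), (0, 90, 0.0), (8.5, 110, 935.0)],
)
def test_session_rpe_is_rating_times_minutes(rpe, duration, expected):
    assert session_rpe(rpe, duration) == expected


def test_session_rpe_rejects_bad_inputs():
    with pytest.raises(ValueError):
        session_rpe(7, 0)
    with pytest.raises(ValueError):
        session_rpe(11, 60)


def test_monotony_constant_week_is_undefined():
    assert math.isnan(training_monotony([400.0] * 7))


@pytest.mark.parametrize(
    "loads,expected",
    [
        ([500, 400, 300, 600, 200, 0, 0], 1.2209),
        ([0, 0, 0, 0, 0, 0, 700], 0.378),
    ],
)
def test_monotony_mean_over_sample_sd(loads, expected):
    loads = np.asarray(loads, dtype=float)
    oracle = loads.mean() / loads.std(ddof=1)
    assert training_monotony(loads) == pytest.approx(oracle)
    assert training_monotony(loads) == pytest.approx(expected, abs=5e-4)


def test_monotony_needs_seven_days():
    with pytest.raises(ValueError):
        training_monotony([100.0] * 6)


def test_strain_is_load_times_monotony():
    assert training_strain(2000.0, 1.0) == 2000.0
    assert training_strain(2000.0, 1.2364) == pytest.approx(2472.8)
    assert training_strain(0.0, 2.0) == 0.0
    assert math.isnan(training_strain(2000.0, math.nan))


def test_acwr_rolling_four_week_ratio():
    assert acwr([2000.0] * 8, 6) == pytest.approx(1.0)
    assert acwr([1000, 1000, 1000, 2000], 4) == pytest.approx(1.6)
    assert math.isnan(acwr([0, 0, 0, 0], 4))  # zero chronic load
    assert math.isnan(acwr([1000] * 8, 3))  # needs 4 weeks of history
    # excluding the acute week from the chronic mean
    assert acwr([1000, 1000, 1000, 2000], 4, exclude_current=True) == pytest.approx(2.0)


@pytest.mark.parametrize(
    "pb,t,expected",
    [(60.0, 60.0, 100.0), (62.0, 60.5, 105.02), (60.0, 120.0, 25.0)],
)
def test_percent_pbt_squared_time_ratio(pb, t, expected):
    assert percent_pbt(pb, t) == pytest.approx(expected, abs=5e-3)


@given(st.floats(min_value=1.0, max_value=1000.0))
def test_percent_pbt_equal_times_give_100(pb):
    assert percent_pbt(pb, pb) == pytest.approx(100.0)


@given(
    st.floats(min_value=10.0, max_value=500.0),
    st.floats(min_value=10.0, max_value=500.0),
    st.floats(min_value=1.01, max_value=2.0),
)
def test_percent_pbt_strictly_decreasing_in_time(pb, t, factor):
    assert percent_pbt(pb, t * factor) < percent_pbt(pb, t)


def test_total_mood_disturbance_sum_minus_vigour():
    def entry(a, c, d, f, t, v):
        return PomsEntry(date(2013, 10, 6), a, c, d, f, t, v)

    assert total_mood_disturbance(entry(0, 0, 0, 0, 0, 0)) == 0.0
    assert total_mood_disturbance(entry(2, 3, 1, 4, 2, 10)) == 2.0
    assert total_mood_disturbance(entry(0, 0, 0, 0, 0, 12)) == -12.0


@pytest.mark.parametrize("z,expected", [(105.9, 1), (100.0, -1), (99.2, -1)])
def test_binarize_threshold_at_100(z, expected):
    assert binarize_pbt(z) == expected


@given(st.floats(min_value=-5.0, max_value=5.0))
def test_binarize_adaptation_iff_above_100(delta):
    z = 100.0 + delta
    assert (binarize_pbt(z) == 1) == (z > 100.0)


def test_normalize_divides_by_maximum():
    assert normalize_series([2, 4, 8]).tolist() == [0.25, 0.5, 1.0]
    assert normalize_series([5]).tolist() == [1.0]
    with pytest.raises(ValueError):
        normalize_series([0.0, 0.0])


@given(
    st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=30).filter(
        lambda v: max(v) > 0
    )
)
def test_normalize_unit_maximum_and_order(values):
    out = normalize_series(values)
    assert np.nanmax(out) == pytest.approx(1.0)
    order = np.argsort(values, kind="stable")
    assert np.array_equal(np.argsort(out, kind="stable"), order)


def test_quartiles_reproduce_printed_swimmer_table():
    """All 65 printed quartile bands follow from the printed value columns."""
    table = swimmer_characteristics()
    assert len(table) == 13
    for value_col, quartile_col in SWIMMER_TABLE_QUARTILE_COLUMNS.items():
        computed = assign_quartiles(table[value_col].to_numpy())
        assert computed.tolist() == table[quartile_col].tolist(), value_col


def test_quartile_ties_share_minimum_rank_band():
    table = swimmer_characteristics()
    fifteens = table[table["age"] == 15]
    assert set(fifteens["swimmer"]) == {"B6", "B29", "D21", "D22"}
    q = assign_quartiles(table["age"].to_numpy())
    assert all(q[table["age"].to_numpy() == 15] == 1)


def test_quartiles_distinct_sorted_values():
    assert assign_quartiles([1, 2, 3, 4]).tolist() == [1, 2, 3, 4]
    with pytest.raises(ValueError):
        assign_quartiles([1, 2, 3])


def test_weekly_aggregate_best_pbt_and_missing_recovery():
    series = make_series(
        [
            {"sessions": [(5, 60, 3000)] * 3, "recovery": [5, 6], "pbt": [99.1, 101.2]},
            {"sessions": [(6, 60, 4000)] * 3},
        ]
    )
    m = weekly_aggregate(series)
    assert len(m) == 2
    assert m[0].best_pbt == pytest.approx(101.2, abs=1e-9)
    assert m[0].mean_recovery == pytest.approx(5.5)
    assert math.isnan(m[1].mean_recovery)
    assert m[1].best_pbt is None


def test_weekly_aggregate_empty_week_zero_load_undefined_monotony():
    series = make_series(
        [{"sessions": [(5, 60, 3000)] * 3}, {}], n_weeks=2
    )
    m = weekly_aggregate(series)
    assert m[1].mean_distance == 0.0
    assert m[1].mean_session_rpe == 0.0
    assert math.isnan(m[1].monotony)
    assert math.isnan(m[1].strain)


def test_weekly_aggregate_full_season_cardinality():
    from adaptgeom import CohortConfig, simulate_athlete

    series = simulate_athlete(CohortConfig(seed=11), 0)
    assert len(weekly_aggregate(series)) == 26


def test_build_combination_normalises_selected_metrics():
    series = make_series(
        [
            {"sessions": [(5, 60, 3000)] * 3, "recovery": [5], "pbt": [103.0]},
            {"sessions": [(6, 70, 5000)] * 4, "recovery": [4]},
            {"sessions": [(4, 50, 2000)] * 2, "recovery": [6], "pbt": [98.0]},
            {"sessions": [(5, 60, 3500)] * 3, "recovery": [5]},
        ]
    )
    metrics = weekly_aggregate(series)
    triplets = build_combination(metrics, 1)
    dist = np.array([m.mean_distance for m in metrics])
    assert [t.x for t in triplets] == pytest.approx((dist / dist.max()).tolist())
    assert all(0.0 <= t.x <= 1.0 and 0.0 <= t.y <= 1.0 for t in triplets)
    assert [t.label for t in triplets if t.label is not None] == [1, -1]

    with pytest.raises(ValueError):
        build_combination(metrics, 6)


def test_combination_five_drops_weeks_without_acwr():
    spec = {"sessions": [(5, 60, 3000), (6, 70, 4000)], "recovery": [5]}
    series = make_series([spec] * 6)
    weeks, _, _, _ = raw_combination(weekly_aggregate(series), 5)
    assert weeks.min() == 4  # ACWR is undefined in weeks 1-3


def test_prerequisites_accept_and_reject():
    base = {"sessions": [(5, 60, 3000)] * 3, "recovery": [5, 5]}
    ok = make_series([dict(base, pbt=[103.0]), dict(base, pbt=[98.0]), base])
    assert apply_prerequisites(ok, 0.8, {"wellbeing": 0.9, "poms": 0.85}).include

    one_sided = make_series([dict(base, pbt=[103.0]), dict(base, pbt=[100.5]), base])
    decision = apply_prerequisites(one_sided, 0.9, {"wellbeing": 0.9})
    assert not decision.include
    assert any("under 100%" in r for r in decision.failed)

    boundary = apply_prerequisites(ok, 0.9, {"wellbeing": 0.80})
    assert not boundary.include  # strict inequality: exactly 80% fails

    attendance = apply_prerequisites(ok, 0.75, {"wellbeing": 0.9})
    assert not attendance.include

    incomplete = make_series(
        [dict(base, pbt=[103.0]), {"sessions": [(5, 60, 3000)], "pbt": [98.0]}]
    )
    decision = apply_prerequisites(incomplete, 0.9, {"wellbeing": 0.9})
    assert any("incomplete" in r for r in decision.failed)
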