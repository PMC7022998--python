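"""Dissimilarities, pattern clustering, convexification and the region map."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shapely
from adaptgeom import (
    LabelledPoint,
    bray_curtis,
    build_domain_map,
    chebyshev,
    classify_point,
    cluster_patterns,
    convexify,
    fit_domain_map,
    norm_sq_euclidean,
    select_sparsest_solution,
)
from adaptgeom.geometry import (
    METRICS,
    NEUTRAL,
    ClusteringSolution,
    build_patterns,
)

unit_coord = st.floats(min_value=0.0, max_value=1.0)
unit_point = st.tuples(unit_coord, unit_coord)


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------


def test_bray_curtis_values():
    assert bray_curtis((0.3, 0.4), (0.3, 0.4)) == 0.0
    assert bray_curtis((0.0, 0.0), (0.0, 0.0)) == 0.0
    assert bray_curtis((1, 0), (0, 1)) == pytest.approx(1.0)
    assert bray_curtis((0.2, 0.4), (0.4, 0.2)) == pytest.approx(0.4 / 1.2)


def test_chebyshev_values():
    assert chebyshev((0.5, 0.5), (0.5, 0.5)) == 0.0
    assert chebyshev((0, 0), (0.3, 0.7)) == pytest.approx(0.7)


def test_norm_sq_euclidean_values():
    assert norm_sq_euclidean((0.4, 0.4), (0.4, 0.4)) == 0.0
    # centred vectors are exact opposites -> maximal dissimilarity
    assert norm_sq_euclidean((1.0, 0.0), (0.0, 1.0)) == pytest.approx(1.0)
    # oracle recomputation of the half-normalised form
    u, v = np.array([0.8, 0.2]), np.array([0.1, 0.5])
    uc, vc = u - u.mean(), v - v.mean()
    expected = 0.5 * np.sum((uc - vc) ** 2) / (np.sum(uc**2) + np.sum(vc**2))
    assert norm_sq_euclidean(u, v) == pytest.approx(expected)


@given(unit_point, unit_point)
def test_dissimilarities_symmetric_and_bounded(u, v):
    for fn in (bray_curtis, chebyshev, norm_sq_euclidean):
        assert fn(u, v) == pytest.approx(fn(v, u))
        assert fn(u, v) >= 0.0
    assert norm_sq_euclidean(u, v) <= 1.0 + 1e-12
    assert chebyshev(u, v) <= 1.0


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _blob(cx, cy, label, week0, n=4, spread=0.02):
    offsets = np.linspace(-spread, spread, n)
    return [
        LabelledPoint(week0 + i, (cx + o, cy + o / 2), label)
        for i, o in enumerate(offsets)
    ]


@pytest.mark.parametrize("metric", METRICS)
def test_two_separated_blobs_yield_two_clusters(metric):
    points = (
        _blob(0.2, 0.2, 1, 1)
        + _blob(0.8, 0.8, 1, 5)
        + [LabelledPoint(9, (0.5, 0.1), -1)]
    )
    solution = cluster_patterns(points, metric)
    assert solution.k_per_class[1] == 2
    assert solution.k_per_class[-1] == 1  # singleton class stays one cluster


def test_clustering_invariant_to_input_order(separable_points):
    solution = cluster_patterns(separable_points, "bray_curtis")
    reordered = list(reversed(separable_points))
    solution2 = cluster_patterns(reordered, "bray_curtis")

    def partition(points, sol):
        groups = {}
        for i, cid in sol.assignments.items():
            groups.setdefault(cid, set()).add(points[i].week)
        return {frozenset(g) for g in groups.values()}

    assert partition(separable_points, solution) == partition(reordered, solution2)


def test_cluster_patterns_requires_both_classes(separable_points):
    with pytest.raises(ValueError):
        cluster_patterns([p for p in separable_points if p.label == 1], "chebyshev")


def test_sparsest_solution_selection():
    def sol(metric, total, ch):
        return ClusteringSolution(metric, {i: i for i in range(total)}, {1: total}, ch)

    picked = select_sparsest_solution(
        [sol("bray_curtis", 3, 9.0), sol("chebyshev", 2, 5.0), sol("norm_sq_euclidean", 4, 1.0)]
    )
    assert picked.total_clusters == 2
    # tie on count -> higher Calinski-Harabasz wins
    picked = select_sparsest_solution(
        [sol("bray_curtis", 2, 5.0), sol("chebyshev", 2, 8.0)]
    )
    assert picked.metric == "chebyshev"
    # full tie -> fixed metric order
    picked = select_sparsest_solution(
        [sol("chebyshev", 2, 5.0), sol("bray_curtis", 2, 5.0)]
    )
    assert picked.metric == "bray_curtis"


# ---------------------------------------------------------------------------
# Convexification
# ---------------------------------------------------------------------------


def test_convexify_square_and_degenerate_cases():
    square = np.array([[0.2, 0.2], [0.2, 0.8], [0.8, 0.8], [0.8, 0.2]])
    pattern = convexify(square, 0, 1)
    assert pattern.hull.area == pytest.approx(0.36)

    disk = convexify(np.array([[0.5, 0.5]]), 1, -1, buffer_radius=0.02)
    assert disk.hull.area == pytest.approx(np.pi * 0.02**2, rel=1e-2)
    assert disk.hull.contains(shapely.Point(0.5, 0.5))

    segment = convexify(np.array([[0.2, 0.5], [0.4, 0.5]]), 2, 1, buffer_radius=0.02)
    assert segment.hull.area > 0.0


@given(
    st.lists(unit_point, min_size=1, max_size=10),
)
def test_convex_hull_contains_every_cluster_point(coords):
    pattern = convexify(np.array(coords), 0, 1)
    for c in coords:
        assert pattern.hull.distance(shapely.Point(c)) < 1e-9


# ---------------------------------------------------------------------------
# Domain map
# ---------------------------------------------------------------------------


def test_symmetric_halves_give_vertical_midline(mirror_points):
    dm = fit_domain_map(mirror_points, layer_width=1e-4, grid_resolution=128)
    # the boundary hugs x = 0.5 and the areas split evenly
    for line in dm.boundary:
        assert np.all(np.abs(line[:, 0] - 0.5) < 0.04)
    frac_plus = np.mean(dm.labels == 1)
    frac_minus = np.mean(dm.labels == -1)
    assert frac_plus == pytest.approx(frac_minus, abs=0.02)
    assert frac_plus == pytest.approx(0.5, abs=0.02)


def test_hull_interiors_keep_their_label(separable_points):
    solutions = [cluster_patterns(separable_points, m) for m in METRICS]
    patterns = build_patterns(separable_points, select_sparsest_solution(solutions))
    dm = build_domain_map(patterns, layer_width=0.005, grid_resolution=128)
    res = dm.grid_resolution
    centres = (np.arange(res) + 0.5) / res
    xx, yy = np.meshgrid(centres, centres)
    for pattern in dm.patterns:
        inside = shapely.contains_xy(
            pattern.hull.buffer(-2 * dm.layer_width), xx.ravel(), yy.ravel()
        ).reshape(res, res)
        cells = dm.labels[inside]
        assert np.all(cells == pattern.label)


def test_neutral_area_vanishes_with_layer_width(separable_points):
    fracs = []
    for eps in (0.08, 0.02, 0.0):
        dm = fit_domain_map(separable_points, layer_width=eps, grid_resolution=64)
        fracs.append(float(np.mean(dm.labels == NEUTRAL)))
    assert fracs[0] > fracs[1] > fracs[2]
    assert fracs[2] <= 1.0 / 64  # only exact-tie cells may remain


def test_region_map_invariant_to_point_order(separable_points):
    dm1 = fit_domain_map(separable_points, grid_resolution=64)
    dm2 = fit_domain_map(list(reversed(separable_points)), grid_resolution=64)
    assert np.array_equal(dm1.labels, dm2.labels)


def test_grid_resolution_floor(separable_points):
    with pytest.raises(ValueError):
        fit_domain_map(separable_points, grid_resolution=16)


def test_region_of_matches_exhaustive_nearest_hull_scan(separable_points):
    """Brute-force oracle: direct nearest-hull scan over every cell centre."""
    dm = fit_domain_map(
        separable_points, layer_width=0.01, grid_resolution=64, k_max=2
    )
    res = 64
    for i in range(res):
        for j in range(res):
            q = ((j + 0.5) / res, (i + 0.5) / res)
            pt = shapely.Point(q)
            dp = min(
                pt.distance(p.hull) for p in dm.patterns if p.label == 1
            )
            dmn = min(
                pt.distance(p.hull) for p in dm.patterns if p.label == -1
            )
            f = dmn - dp
            if dp == 0.0 and dmn == 0.0:
                continue  # overlap cells use the centroid rule
            expected = NEUTRAL if abs(f) <= 0.01 else (1 if f > 0 else -1)
            assert dm.region_of(q) == expected, (i, j)


def test_classify_point_rules(separable_points):
    dm = fit_domain_map(separable_points, layer_width=0.05, grid_resolution=64)
    assert classify_point(dm, (0.2, 0.45)) == 1  # deep inside a +1 hull
    assert classify_point(dm, (0.78, 0.55)) == -1
    # neutral-layer point resolves to the nearest labelled region
    mid = (0.5, 0.5)
    assert dm.region_of(mid) == NEUTRAL
    assert classify_point(dm, mid) in (-1, 1)
    with pytest.raises(ValueError):
        classify_point(dm, (1.2, 0.5))


def test_training_points_classified_correctly_when_separable(separable_points):
    dm = fit_domain_map(separable_points, grid_resolution=64)
    for p in separable_points:
        assert classify_point(dm, p.p) == p.label


def test_domain_map_json_round_trip(separable_points):
    dm = fit_domain_map(separable_points, grid_resolution=64)
    from adaptgeom.geometry import DomainMap

    restored = DomainMap.from_json(dm.to_json())
    assert restored.grid_resolution == dm.grid_resolution
    assert np.array_equal(restored.labels, dm.labels)
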