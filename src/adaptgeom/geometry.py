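"""Geometric construction of adaptation / maladaptation regions.

The classifier is built, not trained: labelled weekly points in the unit
square are clustered per class (average-linkage agglomerative clustering
under three dissimilarities — Bray-Curtis, Chebyshev, normalised squared
Euclidean — with the cluster count picked by the Calinski-Harabasz
criterion and the sparsest of the three solutions retained), each cluster is
convexified into its domain of influence, and every point of the square is
assigned the label of the nearest hull. A thin neutral layer of width
``layer_width`` disconnects the two domains along their frontier, and the
separating boundary is extracted as the zero contour of the signed
point-to-hull distance field on a regular grid.

The resulting piecewise-constant region map *is* the network: its activation
is the sign of region membership, so the construction is deterministic and
needs no iterative weight fitting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import contourpy
import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon, box
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import calinski_harabasz_score

NEUTRAL = 0
UNIT_SQUARE = box(0.0, 0.0, 1.0, 1.0)

#: Fixed metric order, also the final tie-break in solution selection.
METRICS = ("bray_curtis", "chebyshev", "norm_sq_euclidean")


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v); 0 for two zero points."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    denom = float(np.sum(u + v))
    if denom == 0.0:
        return 0.0
    return float(np.sum(np.abs(u - v)) / denom)


def chebyshev(u: Sequence[float], v: Sequence[float]) -> float:
    """Chebyshev (maximum-coordinate) distance."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(np.max(np.abs(u - v)))


def norm_sq_euclidean(u: Sequence[float], v: Sequence[float]) -> float:
    """Normalised squared Euclidean distance in [0, 1].

    Each vector is centred by its own component mean, and the squared
    difference is scaled against the total squared magnitude:
    ``1/2 * ||u' - v'||^2 / (||u'||^2 + ||v'||^2)`` with ``u' = u - mean(u)``.
    Zero when the centred vectors coincide (e.g. u = v), and 1 for centred
    vectors that are exact opposites; 0 by convention when both centred
    vectors vanish.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean()
    vc = v - v.mean()
    denom = float(np.sum(uc**2) + np.sum(vc**2))
    if denom == 0.0:
        return 0.0
    return float(0.5 * np.sum((uc - vc) ** 2) / denom)


_METRIC_FUNCS: dict[str, Callable[[Sequence[float], Sequence[float]], float]] = {
    "bray_curtis": bray_curtis,
    "chebyshev": chebyshev,
    "norm_sq_euclidean": norm_sq_euclidean,
}


def dissimilarity_matrix(points: np.ndarray, metric: str) -> np.ndarray:
    fn = _METRIC_FUNCS[metric]
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(points[i], points[j])
    return d


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelledPoint:
    """A competition week embedded in the unit square with its +/-1 label."""

    week: int
    p: tuple[float, float]
    label: int

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError("label must be +1 or -1")
        if not (0.0 <= self.p[0] <= 1.0 and 0.0 <= self.p[1] <= 1.0):
            raise ValueError("point must lie in the unit square")


@dataclass
class ClusteringSolution:
    """Per-class partition of the labelled points under one dissimilarity."""

    metric: str
    assignments: dict[int, int]  # point index -> global cluster id
    k_per_class: dict[int, int]  # label -> cluster count
    ch_score: float  # summed CH over classes where defined

    @property
    def total_clusters(self) -> int:
        return sum(self.k_per_class.values())


def _cluster_class(points: np.ndarray, metric: str, k_max: int) -> np.ndarray:
    """Average-linkage partition of one class; k maximises Calinski-Harabasz.

    CH needs 2 <= k <= n-1, so classes of fewer than 3 points form a single
    cluster. Returns 0-based cluster labels per point.
    """
    n = len(points)
    if n < 3 or k_max < 2:
        return np.zeros(n, dtype=int)
    d = dissimilarity_matrix(points, metric)
    best_labels = np.zeros(n, dtype=int)
    best_ch = -math.inf
    for k in range(2, min(n - 1, k_max) + 1):
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        )
        labels = model.fit_predict(d)
        # CH is variance-based, evaluated in Euclidean coordinates
        ch = calinski_harabasz_score(points, labels)
        if ch > best_ch:
            best_ch = ch
            best_labels = labels
    single = np.zeros(n, dtype=int)
    return best_labels if best_ch > -math.inf else single


def cluster_patterns(
    points: Sequence[LabelledPoint], metric: str, k_max: int = 4
) -> ClusteringSolution:
    """Cluster each label class separately under one dissimilarity."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    labels = {p.label for p in points}
    if labels != {-1, 1}:
        raise ValueError("need at least one point of each label class")
    assignments: dict[int, int] = {}
    k_per_class: dict[int, int] = {}
    ch_total = 0.0
    next_id = 0
    for cls in (1, -1):
        idx = [i for i, p in enumerate(points) if p.label == cls]
        coords = np.array([points[i].p for i in idx])
        part = _cluster_class(coords, metric, k_max)
        k = int(part.max()) + 1
        k_per_class[cls] = k
        if k > 1:
            ch_total += calinski_harabasz_score(coords, part)
        for local_i, global_i in enumerate(idx):
            assignments[global_i] = next_id + int(part[local_i])
        next_id += k
    return ClusteringSolution(metric, assignments, k_per_class, ch_total)


def select_sparsest_solution(
    solutions: Sequence[ClusteringSolution],
) -> ClusteringSolution:
    """Keep the solution with the fewest patterns.

    Ties break to the higher Calinski-Harabasz score, then to the fixed
    metric order (bray_curtis, chebyshev, norm_sq_euclidean).
    """
    if not solutions:
        raise ValueError("no clustering solutions given")
    return min(
        solutions,
        key=lambda s: (s.total_clusters, -s.ch_score, METRICS.index(s.metric)),
    )


# ---------------------------------------------------------------------------
# Convexification
# ---------------------------------------------------------------------------


@dataclass
class ConvexPattern:
    """A cluster's convex domain of influence in the unit square."""

    cluster_id: int
    label: int
    hull: Polygon
    vertices: np.ndarray

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.hull.centroid
        return (c.x, c.y)


def convexify(
    coords: np.ndarray, cluster_id: int, label: int, buffer_radius: float = 0.02
) -> ConvexPattern:
    """Convex hull of a cluster, buffered when degenerate.

    Singletons, pairs and collinear clusters have zero-area hulls; these are
    inflated by ``buffer_radius`` into a disk/capsule and clipped back to the
    unit square so every pattern has positive area.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) == 0:
        raise ValueError("cannot convexify an empty cluster")
    hull = MultiPoint([tuple(c) for c in coords]).convex_hull
    if hull.area == 0.0:
        hull = hull.buffer(buffer_radius).intersection(UNIT_SQUARE)
    return ConvexPattern(
        cluster_id=cluster_id,
        label=label,
        hull=hull,
        vertices=np.asarray(hull.exterior.coords),
    )


def build_patterns(
    points: Sequence[LabelledPoint],
    solution: ClusteringSolution,
    buffer_radius: float = 0.02,
) -> list[ConvexPattern]:
    """Convexify every cluster of a selected clustering solution."""
    ids = sorted(set(solution.assignments.values()))
    patterns = []
    for cid in ids:
        idx = [i for i, c in solution.assignments.items() if c == cid]
        label = points[idx[0]].label
        coords = np.array([points[i].p for i in idx])
        patterns.append(convexify(coords, cid, label, buffer_radius))
    return patterns


# ---------------------------------------------------------------------------
# Domain map
# ---------------------------------------------------------------------------


@dataclass
class DomainMap:
    """Partition of the unit square into +1 / -1 / neutral regions.

    ``labels`` is a ``(res, res)`` integer grid over cell centres (row index
    = y, column index = x), ``signed_field`` the corresponding
    ``d_minus - d_plus`` point-to-hull distance difference, and ``boundary``
    the zero-contour polylines of that field.
    """

    patterns: list[ConvexPattern]
    layer_width: float
    grid_resolution: int
    labels: np.ndarray = field(repr=False)
    signed_field: np.ndarray = field(repr=False)
    boundary: list[np.ndarray] = field(repr=False)

    def region_of(self, q: Sequence[float]) -> int:
        """Region label (+1, -1 or 0 = neutral) of the grid cell holding q."""
        x, y = float(q[0]), float(q[1])
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(f"point {q} outside the unit square")
        res = self.grid_resolution
        i = min(int(y * res), res - 1)
        j = min(int(x * res), res - 1)
        return int(self.labels[i, j])

    def to_json(self) -> str:
        doc = {
            "layer_width": self.layer_width,
            "grid_resolution": self.grid_resolution,
            "patterns": [
                {
                    "cluster_id": p.cluster_id,
                    "label": p.label,
                    "vertices": np.asarray(p.vertices).tolist(),
                }
                for p in self.patterns
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DomainMap":
        doc = json.loads(text)
        patterns = [
            ConvexPattern(
                cluster_id=p["cluster_id"],
                label=p["label"],
                hull=Polygon(p["vertices"]),
                vertices=np.asarray(p["vertices"]),
            )
            for p in doc["patterns"]
        ]
        return build_domain_map(
            patterns,
            layer_width=doc["layer_width"],
            grid_resolution=doc["grid_resolution"],
        )


def _grid_centres(res: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(res) + 0.5) / res
    return np.meshgrid(c, c)  # xx[i, j] = c[j], yy[i, j] = c[i]


def build_domain_map(
    patterns: Sequence[ConvexPattern],
    layer_width: float = 0.01,
    grid_resolution: int = 256,
) -> DomainMap:
    """Assign every grid cell of the unit square to a region.

    Each cell centre takes the label of the pattern whose hull is nearest in
    Euclidean point-to-polygon distance (0 inside). Cells inside hulls of
    both labels are decided by the nearest hull centroid. Cells within
    ``layer_width`` of the inter-label frontier (|d_minus - d_plus| <=
    layer_width) form the neutral separating layer, and the boundary is the
    zero contour of the signed field.
    """
    if grid_resolution < 32:
        raise ValueError("grid_resolution must be >= 32 for usable integration")
    if layer_width < 0:
        raise ValueError("layer_width must be >= 0")
    plus = [p for p in patterns if p.label == 1]
    minus = [p for p in patterns if p.label == -1]
    if not plus or not minus:
        raise ValueError("need at least one pattern per label class")

    res = grid_resolution
    xx, yy = _grid_centres(res)
    pts = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]))

    def min_dist(group: list[ConvexPattern]) -> np.ndarray:
        d = np.min(
            np.stack([shapely.distance(pts, p.hull) for p in group]), axis=0
        )
        return d.reshape(res, res)

    d_plus = min_dist(plus)
    d_minus = min_dist(minus)
    f = d_minus - d_plus

    labels = np.where(f > 0, 1, -1).astype(int)
    labels[np.abs(f) <= layer_width] = NEUTRAL

    # cells inside opposite-label hulls: nearest hull centroid wins, never neutral
    overlap = (d_plus == 0.0) & (d_minus == 0.0)
    if overlap.any():
        cells = np.column_stack([xx[overlap], yy[overlap]])
        cp = np.min(
            np.stack(
                [np.hypot(*(cells - p.centroid).T) for p in plus]
            ),
            axis=0,
        )
        cm = np.min(
            np.stack(
                [np.hypot(*(cells - p.centroid).T) for p in minus]
            ),
            axis=0,
        )
        labels[overlap] = np.where(cp <= cm, 1, -1)

    gen = contourpy.contour_generator(xx, yy, f)
    boundary = [np.asarray(line) for line in gen.lines(0.0)]

    return DomainMap(
        patterns=list(patterns),
        layer_width=layer_width,
        grid_resolution=res,
        labels=labels,
        signed_field=f,
        boundary=boundary,
    )


def classify_point(domain_map: DomainMap, q: Sequence[float]) -> int:
    """Hard +/-1 classification of a point, resolving the neutral layer.

    Applies the map's nearest-hull rule to ``q`` exactly (the grid in
    :meth:`DomainMap.region_of` only discretises this same rule for area
    integration): a point in the neutral layer, or whose exact distances
    disagree with its cell's centre, is assigned the nearest labelled
    region, with ties broken by the nearest hull centroid.
    """
    x, y = float(q[0]), float(q[1])
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError(f"point {q} outside the unit square")
    pt = shapely.points(x, y)
    dp = min(shapely.distance(pt, p.hull) for p in domain_map.patterns if p.label == 1)
    dm = min(shapely.distance(pt, p.hull) for p in domain_map.patterns if p.label == -1)
    if dp < dm:
        return 1
    if dm < dp:
        return -1
    cp = min(
        math.hypot(q[0] - p.centroid[0], q[1] - p.centroid[1])
        for p in domain_map.patterns
        if p.label == 1
    )
    cm = min(
        math.hypot(q[0] - p.centroid[0], q[1] - p.centroid[1])
        for p in domain_map.patterns
        if p.label == -1
    )
    return 1 if cp <= cm else -1


def fit_domain_map(
    points: Sequence[LabelledPoint],
    *,
    k_max: int = 4,
    layer_width: float = 0.01,
    buffer_radius: float = 0.02,
    grid_resolution: int = 256,
) -> DomainMap:
    """Full geometric construction from labelled points to region map."""
    solutions = [cluster_patterns(points, m, k_max) for m in METRICS]
    best = select_sparsest_solution(solutions)
    patterns = build_patterns(points, best, buffer_radius)
    return build_domain_map(patterns, layer_width, grid_resolution)
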