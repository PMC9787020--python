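"""Search-area polygons (alpha shapes) and the team overlap proportion.

Each player's search area is the tightest single bounding polygon around
its visited 5 Hz positions, constructed as an *alpha shape*: from the
Delaunay triangulation of the points, triangles whose circumradius
exceeds ``1/alpha`` are discarded and the rest are unioned.  The shape
parameter is found by bisection between 0 (the convex hull) and an upper
bound derived from the median nearest-neighbor spacing, selecting the
largest ``alpha`` whose shape is a single polygon containing every input
point.  If the search fails to converge the convex hull is used.  Holes
in the alpha shape are permitted and excluded from the area.

Division of labor is then quantified as the proportion of overlapping
search area: the area covered by at least two players' polygons (the
union of all pairwise intersections — triple-covered regions count once)
divided by the area of the union of all polygons.  0 means the team
cleanly partitioned the space; 1 means everyone searched the same
locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint
from shapely.ops import unary_union

from .simulate import TrialLog
from .timeseries import ANALYSIS_HZ, downsample

__all__ = [
    "SearchPolygon",
    "OverlapResult",
    "alpha_shape",
    "overlap_proportion",
    "trial_search_polygons",
    "trial_overlap",
]

_BISECTION_TOL = 1e-4
_BISECTION_CAP = 1000


@dataclass
class SearchPolygon:
    """One player's bounding search polygon."""

    polygon: object  # shapely geometry
    method: str  # "alpha_shape" | "convex_hull"
    player: str | None = None
    degenerate: bool = False
    alpha: float = 0.0

    @property
    def area(self) -> float:
        return float(self.polygon.area)


@dataclass
class OverlapResult:
    """Team-level overlap of search polygons.

    ``proportion`` is ``overlap_area / total_area``; when the total area
    is zero the proportion is undefined and reported as NaN with
    ``degenerate`` set.
    """

    proportion: float
    overlap_area: float
    total_area: float
    per_player_areas: list[float] = field(default_factory=list)
    degenerate: bool = False


def _circumradii(points: np.ndarray, tri: Delaunay) -> np.ndarray:
    """Circumradius of every Delaunay triangle (inf for degenerate ones)."""
    a = points[tri.simplices[:, 0]]
    b = points[tri.simplices[:, 1]]
    c = points[tri.simplices[:, 2]]
    la = np.hypot(*(b - c).T)
    lb = np.hypot(*(a - c).T)
    lc = np.hypot(*(a - b).T)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)


def _keep_mask(circumradius: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return np.ones(circumradius.size, dtype=bool)
    return circumradius < 1.0 / alpha


def _acceptable_mask(
    tri: Delaunay, keep: np.ndarray, n_points: int
) -> bool:
    """Combinatorial acceptance test for one alpha level.

    The kept triangles must use every input point as a vertex (points are
    triangulation vertices, so vertex coverage is exact containment) and
    must form a single edge-connected component, which guarantees the
    union is one polygon.
    """
    if not keep.any():
        return False
    if np.unique(tri.simplices[keep]).size < n_points:
        return False
    kept_idx = np.flatnonzero(keep)
    relabel = np.full(keep.size, -1)
    relabel[kept_idx] = np.arange(kept_idx.size)
    nbr = tri.neighbors[kept_idx]  # (m, 3), -1 = no neighbor
    valid = (nbr >= 0) & keep[np.clip(nbr, 0, None)]
    rows = np.repeat(np.arange(kept_idx.size), 3)[valid.ravel()]
    cols = relabel[nbr.ravel()[valid.ravel()]]
    graph = coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(kept_idx.size,) * 2
    )
    n_comp = connected_components(graph, directed=False)[0]
    return n_comp == 1


def _triangle_union(points: np.ndarray, tri: Delaunay, keep: np.ndarray) -> object:
    """Shapely union of the kept Delaunay triangles."""
    coords = np.stack(
        (
            points[tri.simplices[:, 0]],
            points[tri.simplices[:, 1]],
            points[tri.simplices[:, 2]],
            points[tri.simplices[:, 0]],
        ),
        axis=1,
    )[keep]
    return shapely.union_all(shapely.polygons(coords))


def _contains_all(shape: object, points: np.ndarray, tol: float = 1e-9) -> bool:
    geoms = shapely.points(points)
    ok = shapely.covers(shape, geoms) | shapely.dwithin(shape, geoms, tol)
    return bool(np.all(ok))


def alpha_shape(points: np.ndarray, player: str | None = None) -> SearchPolygon:
    """Tightest single bounding polygon of a planar point set.

    Bisects the alpha parameter on ``[0, alpha_max]`` (``alpha_max`` from
    the median nearest-neighbor spacing) for the largest value whose
    triangle union is one valid polygon covering all points; falls back
    to the convex hull when no positive alpha qualifies.  Fewer than
    three points, or a collinear set, yield a degenerate result with zero
    area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    pts = np.unique(pts, axis=0)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if pts.shape[0] < 3 or hull.area == 0.0:
        return SearchPolygon(polygon=hull, method="convex_hull", player=player,
                             degenerate=True)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return SearchPolygon(polygon=hull, method="convex_hull", player=player,
                             degenerate=True)

    spacing = np.median(cKDTree(pts).query(pts, k=2)[0][:, 1])
    if not spacing > 0:
        return SearchPolygon(polygon=hull, method="convex_hull", player=player,
                             degenerate=True)
    alpha_hi = 4.0 / spacing
    circumradius = _circumradii(pts, tri)
    n_points = pts.shape[0]

    def acceptable(alpha: float) -> bool:
        return _acceptable_mask(tri, _keep_mask(circumradius, alpha), n_points)

    if acceptable(alpha_hi):
        best_alpha = alpha_hi
    else:
        lo, hi = 0.0, alpha_hi
        iterations = 0
        while hi - lo > _BISECTION_TOL * alpha_hi:
            iterations += 1
            if iterations > _BISECTION_CAP:
                # Cap reached without convergence: stated hull fallback.
                return SearchPolygon(polygon=hull, method="convex_hull", player=player)
            mid = 0.5 * (lo + hi)
            if acceptable(mid):
                lo = mid
            else:
                hi = mid
        best_alpha = lo
    if best_alpha > 0.0:
        shape = _triangle_union(pts, tri, _keep_mask(circumradius, best_alpha))
        if (
            shape.geom_type == "Polygon"
            and not shape.is_empty
            and shape.is_valid
            and _contains_all(shape, pts)
        ):
            return SearchPolygon(polygon=shape, method="alpha_shape", player=player,
                                 alpha=best_alpha)
    return SearchPolygon(polygon=hull, method="convex_hull", player=player)


def overlap_proportion(search_polygons: list[SearchPolygon]) -> OverlapResult:
    """Proportion of the team's total search area covered by >= 2 players.

    The overlapping region is the union of all pairwise polygon
    intersections (a triple-covered patch is counted once); the total is
    the union of all polygons.
    """
    if len(search_polygons) < 2:
        raise ValueError("at least two search polygons are required")
    geoms = [sp.polygon for sp in search_polygons]
    total = unary_union(geoms)
    total_area = float(total.area)
    per_player = [float(g.area) for g in geoms]
    if total_area == 0.0:
        return OverlapResult(
            proportion=float("nan"), overlap_area=0.0, total_area=0.0,
            per_player_areas=per_player, degenerate=True,
        )
    pairwise = [a.intersection(b) for a, b in combinations(geoms, 2)]
    overlap_area = float(unary_union(pairwise).area)
    return OverlapResult(
        proportion=overlap_area / total_area,
        overlap_area=overlap_area,
        total_area=total_area,
        per_player_areas=per_player,
    )


def trial_search_polygons(log: TrialLog) -> list[SearchPolygon]:
    """Per-player search polygons from a trial log.

    Positions are decimated to 5 Hz with the first second removed (the
    same preprocessing as the fluctuation series) before shape
    construction.
    """
    polys = []
    for i in range(log.n_players):
        track = downsample(log.player_pos[:, i, :], log.sample_rate, ANALYSIS_HZ)
        polys.append(alpha_shape(track, player=f"p{i}"))
    return polys


def trial_overlap(log: TrialLog) -> OverlapResult:
    """Team overlap proportion of one trial."""
    return overlap_proportion(trial_search_polygons(log))
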