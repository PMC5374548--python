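"""Flowcell bubble detection from the spatial distribution of polyX reads.

Air bubbles trapped on a flowcell corrupt a roughly circular region of a
tile, and on two-channel chemistry the no-signal reads inside it come out as
polyG. The detector works per lane+tile on the coordinates of polyX-flagged
reads: (1) keep only hits in grid cells whose local density exceeds a
multiple of the tile mean (bubble areas are polyX-dense); (2) cluster the
surviving hits by density reachability (connected components of the
radius-eps neighbour graph) and drop small, oversized or outlier-dominated
clusters; (3) fit the minimum enclosing circle of each cluster and drop
circles with implausible radii. Reads whose coordinates fall strictly inside
a surviving circle are filtered out.

All numeric parameters here (grid size, density fold, neighbour radius,
cluster size, radius bounds) are this package's own defaults, calibrated on
the bundled simulator; see BubbleParams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import radius_neighbors_graph

from .fastq_io import FlowcellCoord

DEFAULT_TILE_WIDTH = 2000.0


@dataclass(frozen=True)
class PolyXHit:
    """One polyX read's flowcell position and its repeated base."""

    coord: FlowcellCoord
    base: str


@dataclass(frozen=True)
class BubbleCircle:
    lane: int
    tile: int
    center_x: float
    center_y: float
    radius: float
    support: int

    def contains(self, x: float, y: float) -> bool:
        return (x - self.center_x) ** 2 + (y - self.center_y) ** 2 < self.radius ** 2

    def to_dict(self) -> dict:
        return {"lane": self.lane, "tile": self.tile,
                "cx": self.center_x, "cy": self.center_y,
                "r": self.radius, "support": self.support}


@dataclass(frozen=True)
class BubbleParams:
    """Detection parameters in tile-coordinate units.

    tile_width sets the spatial scale; derived defaults: neighbour radius
    eps = 1.5 density-filter cells (so hits in adjacent kept cells always
    connect — a smaller eps fragments one bubble into several clusters when
    sparse edge cells are dropped), circle radius bounds
    [tile_width/100, tile_width/4].
    """

    tile_width: float = DEFAULT_TILE_WIDTH
    grid: int = 20
    fold: float = 5.0
    radius_eps: float = 1.5 * DEFAULT_TILE_WIDTH / 20
    min_points: int = 20
    r_min: float = DEFAULT_TILE_WIDTH / 100
    r_max: float = DEFAULT_TILE_WIDTH / 4
    shape_max_ratio: float = 3.0


def density_filter(hits: Sequence[PolyXHit], tile_width: float = DEFAULT_TILE_WIDTH,
                   grid: int = 20, fold: float = 5.0) -> List[PolyXHit]:
    """Keep hits in grid cells denser than fold x the tile's mean cell count.

    The tile is partitioned into grid x grid square cells of side
    tile_width/grid; the mean is n_hits / grid^2.
    """
    if grid < 1:
        raise ValueError(f"grid must be >= 1, got {grid}")
    if fold <= 0:
        raise ValueError(f"fold must be positive, got {fold}")
    if not hits:
        return []
    cell = tile_width / grid
    counts: Dict[Tuple[int, int], int] = {}
    keys = []
    for h in hits:
        key = (min(int(h.coord.x // cell), grid - 1),
               min(int(h.coord.y // cell), grid - 1))
        keys.append(key)
        counts[key] = counts.get(key, 0) + 1
    mean = len(hits) / (grid * grid)
    threshold = fold * mean
    return [h for h, key in zip(hits, keys) if counts[key] > threshold]


def min_enclosing_circle(points: Sequence[Tuple[float, float]]
                         ) -> Tuple[float, float, float]:
    """Smallest circle containing all points (Welzl, move-to-front).

    The optimum is unique, so the result is deterministic regardless of the
    (fixed) processing order used here.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if not pts:
        raise ValueError("min_enclosing_circle requires at least one point")

    def circle_two(p: Tuple[float, float], q: Tuple[float, float]):
        cx = (p[0] + q[0]) / 2.0
        cy = (p[1] + q[1]) / 2.0
        r = math.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
        return cx, cy, r

    def circumcircle(p, q, r):
        ax, ay = p
        bx, by = q
        cx, cy = r
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
              + (cx * cx + cy * cy) * (ay - by)) / d
        uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
              + (cx * cx + cy * cy) * (bx - ax)) / d
        return ux, uy, math.hypot(ax - ux, ay - uy)

    def inside(circle, p, eps=1e-7):
        cx, cy, r = circle
        return math.hypot(p[0] - cx, p[1] - cy) <= r * (1 + eps) + eps

    # iterative incremental construction avoids deep recursion on large inputs
    circle = (pts[0][0], pts[0][1], 0.0)
    for i in range(1, len(pts)):
        if inside(circle, pts[i]):
            continue
        circle = (pts[i][0], pts[i][1], 0.0)
        for j in range(i):
            if inside(circle, pts[j]):
                continue
            circle = circle_two(pts[i], pts[j])
            for k in range(j):
                if inside(circle, pts[k]):
                    continue
                c3 = circumcircle(pts[i], pts[j], pts[k])
                circle = c3 if c3 is not None else circle
    return circle


def cluster_hits(hits: Sequence[PolyXHit], radius_eps: float,
                 min_points: int, r_min: float = 0.0,
                 r_max: float = math.inf,
                 shape_max_ratio: float = 3.0) -> List[List[PolyXHit]]:
    """Density-reachability clustering with size and shape filtering.

    Two hits are neighbours when their Euclidean distance is <= radius_eps;
    clusters are connected components of the neighbour graph with at least
    min_points hits. A cluster is kept when its enclosing-circle radius lies
    in [r_min, r_max] and the ratio of that radius to the mean hit-to-centroid
    distance is <= shape_max_ratio (rejects clusters whose extent is set by a
    few outliers).
    """
    if len(hits) < min_points:
        return []
    xy = np.array([(h.coord.x, h.coord.y) for h in hits], dtype=float)
    graph = radius_neighbors_graph(xy, radius=radius_eps, mode="connectivity",
                                   include_self=False)
    n_comp, labels = connected_components(graph, directed=False)
    clusters: List[List[PolyXHit]] = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if len(idx) < min_points:
            continue
        members = [hits[i] for i in idx]
        pts = xy[idx]
        _, _, radius = min_enclosing_circle(pts)
        if not (r_min <= radius <= r_max):
            continue
        centroid = pts.mean(axis=0)
        spread = float(np.mean(np.hypot(*(pts - centroid).T)))
        if spread > 0 and radius / spread > shape_max_ratio:
            continue
        clusters.append(members)
    return clusters


def detect_bubbles(hits: Iterable[PolyXHit],
                   params: BubbleParams = BubbleParams()) -> List[BubbleCircle]:
    """Full per-tile pipeline: density filter -> clustering -> circle fit ->
    circle filter. Returns all surviving circles across lanes and tiles,
    sorted by (lane, tile, center)."""
    by_tile: Dict[Tuple[int, int], List[PolyXHit]] = {}
    for h in hits:
        by_tile.setdefault((h.coord.lane, h.coord.tile), []).append(h)
    circles: List[BubbleCircle] = []
    for (lane, tile), tile_hits in sorted(by_tile.items()):
        dense = density_filter(tile_hits, tile_width=params.tile_width,
                               grid=params.grid, fold=params.fold)
        clusters = cluster_hits(dense, radius_eps=params.radius_eps,
                                min_points=params.min_points,
                                r_min=params.r_min, r_max=params.r_max,
                                shape_max_ratio=params.shape_max_ratio)
        for cluster in clusters:
            pts = [(h.coord.x, h.coord.y) for h in cluster]
            cx, cy, r = min_enclosing_circle(pts)
            if not (params.r_min <= r <= params.r_max):
                continue
            if len(cluster) < params.min_points:
                continue
            circles.append(BubbleCircle(lane=lane, tile=tile, center_x=cx,
                                        center_y=cy, radius=r,
                                        support=len(cluster)))
    circles.sort(key=lambda c: (c.lane, c.tile, c.center_x, c.center_y))
    return circles
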