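"""Voronoi territories and nearest-neighbor distances of 2D somata.

Microglia tile the healthy cortex almost uniformly, so the Voronoi
territory of each soma (in a 2D maximum-intensity projection) has a
narrow area distribution; plaques disrupt this by aggregating microglia
nearby and depleting adjacent zones, which shows up as small territories
near plaques and enlarged ones around them.

The diagram is clipped to the rectangular ROI by reflecting every seed
across the four ROI edges and tessellating the augmented set: each
original seed's region is then bounded and the clipped regions tile the
ROI exactly (areas sum to the ROI area).  A cell is "complete" when its
territory keeps a positive distance from the ROI boundary — i.e. the
unclipped cell is bounded and contained in the ROI; only complete cells
enter area statistics, border cells are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box

__all__ = [
    "VoronoiCell",
    "TessellationResult",
    "tessellate",
    "area_code",
    "nearest_neighbor_distances",
]

_EPS = 1e-9


@dataclass
class VoronoiCell:
    seed_index: int
    polygon: np.ndarray  # (k, 2) ordered vertices, μm
    area_um2: float
    complete: bool
    nn_distance_um: float


@dataclass
class TessellationResult:
    cells: list[VoronoiCell]
    roi_um: tuple[float, float]
    summary: dict


def _merge_duplicates(points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Collapse seeds closer than ``tol`` (clumped detections) to one."""
    keep: list[int] = []
    tree = cKDTree(points)
    seen = np.zeros(len(points), dtype=bool)
    for i in range(len(points)):
        if seen[i]:
            continue
        close = tree.query_ball_point(points[i], tol)
        for j in close:
            seen[j] = True
        keep.append(i)
    if len(keep) < len(points):
        warnings.warn(f"merged {len(points) - len(keep)} duplicate seed(s)",
                      stacklevel=3)
    return points[keep]


def tessellate(points_um, roi_um: tuple[float, float]) -> TessellationResult:
    """Voronoi tessellation of 2D seeds, clipped to the ROI.

    Requires >= 3 non-collinear seeds inside the ROI.  Clipped areas sum
    to the ROI area; completeness marks cells not touching the border.
    """
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("tessellation needs at least 3 seeds")
    w, h = roi_um
    if np.any(pts < -_EPS) or np.any(pts[:, 0] > w + _EPS) \
            or np.any(pts[:, 1] > h + _EPS):
        raise ValueError("all seeds must lie inside the ROI")
    pts = _merge_duplicates(pts)
    if len(pts) < 3:
        raise ValueError("fewer than 3 distinct seeds after duplicate merge")
    if _collinear(pts):
        raise ValueError("all seeds are collinear; tessellation undefined")

    # reflect seeds across the four ROI edges: every original region of
    # the augmented diagram is bounded and clips exactly to the ROI tile
    left = pts * [-1, 1]
    right = pts * [-1, 1] + [2 * w, 0]
    down = pts * [1, -1]
    up = pts * [1, -1] + [0, 2 * h]
    vor = Voronoi(np.vstack([pts, left, right, down, up]))

    roi_poly = box(0.0, 0.0, w, h)
    cells: list[VoronoiCell] = []
    nn = nearest_neighbor_distances(pts)
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region])
        clipped = poly.intersection(roi_poly)
        verts = np.asarray(clipped.exterior.coords[:-1])
        # complete ⇔ territory strictly inside the ROI
        complete = bool(roi_poly.exterior.distance(poly) > 1e-7)
        cells.append(VoronoiCell(seed_index=i, polygon=verts,
                                 area_um2=float(clipped.area),
                                 complete=complete,
                                 nn_distance_um=float(nn[i])))
    complete_areas = [c.area_um2 for c in cells if c.complete]
    summary = {
        "n_seeds": len(pts),
        "n_complete": len(complete_areas),
        "median_area_um2": (float(np.median(complete_areas))
                            if complete_areas else float("nan")),
        "nn_distance_um": {
            "mean": float(np.mean(nn)),
            "median": float(np.median(nn)),
            "min": float(np.min(nn)),
            "max": float(np.max(nn)),
        },
    }
    return TessellationResult(cells=cells, roi_um=(float(w), float(h)),
                              summary=summary)


def _collinear(pts: np.ndarray) -> bool:
    if len(pts) <= 2:
        return True
    v = pts - pts[0]
    cross = v[1, 0] * v[2:, 1] - v[1, 1] * v[2:, 0]
    return bool(np.abs(cross).max() < _EPS)


def area_code(result: TessellationResult,
              palette_breaks=None, n_classes: int = 4) -> np.ndarray:
    """Assign each complete cell an area class; incomplete cells get −1.

    With explicit ``palette_breaks`` (increasing), class k collects areas
    in (breaks[k−1], breaks[k]]; otherwise breaks are area quantiles of
    the complete cells (``n_classes`` equal-probability classes).
    """
    areas = np.array([c.area_um2 for c in result.cells])
    complete = np.array([c.complete for c in result.cells])
    if palette_breaks is None:
        if not complete.any():
            return np.full(len(areas), -1)
        qs = np.quantile(areas[complete],
                         np.linspace(0, 1, n_classes + 1)[1:-1])
        breaks = np.asarray(qs, dtype=float)
    else:
        breaks = np.asarray(palette_breaks, dtype=float)
        if np.any(np.diff(breaks) <= 0):
            raise ValueError("palette breaks must be strictly increasing")
    classes = np.searchsorted(breaks, areas, side="left")
    classes[~complete] = -1
    return classes


def nearest_neighbor_distances(points_um) -> np.ndarray:
    """For each point, the distance to its closest other point (μm)."""
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("nearest-neighbor distances need >= 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]
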