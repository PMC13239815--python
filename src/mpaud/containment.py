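"""Overlay of UD isopleths on a marine protected area boundary.

Containment is area-based: the percentage of the contour polygon's area
falling inside the MPA boundary. A mass-based secondary statistic
(integrated UD density inside the boundary) is available separately and
clearly labeled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, shape
from shapely.ops import unary_union
from shapely.validation import make_valid

from mpaud.track_io import AzimuthalEquidistant
from mpaud.ud_estimation import UDContour, UDGrid

logger = logging.getLogger(__name__)


@dataclass
class MPABoundary:
    """An MPA boundary polygon in geographic (lon/lat) coordinates."""

    geometry: MultiPolygon  # lon/lat degrees
    name: str = ""
    source: str = ""

    def projected(self, projection: AzimuthalEquidistant) -> MultiPolygon:
        """Boundary in the planar working frame (meters)."""
        def proj_poly(poly: Polygon) -> Polygon:
            ext = np.asarray(poly.exterior.coords)
            x, y = projection.forward(ext[:, 0], ext[:, 1])
            holes = []
            for ring in poly.interiors:
                arr = np.asarray(ring.coords)
                hx, hy = projection.forward(arr[:, 0], arr[:, 1])
                holes.append(list(zip(hx, hy)))
            return Polygon(list(zip(x, y)), holes)

        return MultiPolygon([proj_poly(p) for p in self.geometry.geoms])

    def area_km2(self, projection: AzimuthalEquidistant) -> float:
        return self.projected(projection).area / 1e6


def read_boundary(path, name: str = "") -> MPABoundary:
    """Read an MPA boundary from GeoJSON, dissolving features to one polygon.

    Invalid rings are repaired (with a log message) where possible.
    Shapefile input is not supported; convert to GeoJSON first.
    """
    spath = str(path)
    if spath.lower().endswith((".shp", ".dbf", ".shx")):
        raise ValueError("Shapefile input is not supported; supply GeoJSON")
    with open(path) as fh:
        gj = json.load(fh)

    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"] if f.get("geometry")]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]

    polys = []
    for g in geoms:
        if g.geom_type in ("Polygon", "MultiPolygon"):
            if not g.is_valid:
                logger.warning("invalid ring in %s; attempting repair", path)
                g = make_valid(g)
            polys.append(g)
    if not polys:
        raise ValueError(f"no polygon features in {path}")
    merged = unary_union(polys)
    if isinstance(merged, Polygon):
        merged = MultiPolygon([merged])
    elif not isinstance(merged, MultiPolygon):
        raise ValueError(f"boundary in {path} did not dissolve to a polygon")
    if merged.area <= 0:
        raise ValueError(f"boundary in {path} has zero area")
    return MPABoundary(geometry=merged, name=name or gj.get("name", ""), source=spath)


@dataclass
class ContainmentResult:
    """Percent of a UD isopleth's area inside the MPA boundary."""

    level: float
    contour_km2: float
    intersect_km2: float
    percent_contained: float  # raw double; report rounds to 1 decimal

    def __str__(self) -> str:
        return (f"{int(round(self.level * 100))}% UD: {self.contour_km2:.2f} km², "
                f"{self.percent_contained:.1f}% inside boundary")


def percent_contained(contour: UDContour, boundary: MPABoundary,
                      projection: AzimuthalEquidistant) -> ContainmentResult:
    """Area-based containment of a UD contour (union of all components)."""
    poly = contour.polygons
    if poly.is_empty:
        raise ValueError("empty contour")
    bnd = boundary.projected(projection)
    inter = poly.intersection(bnd)
    pct = 100.0 * inter.area / poly.area
    return ContainmentResult(level=contour.level,
                             contour_km2=poly.area / 1e6,
                             intersect_km2=inter.area / 1e6,
                             percent_contained=float(np.clip(pct, 0.0, 100.0)))


def mass_contained(grid: UDGrid, boundary: MPABoundary,
                   projection: AzimuthalEquidistant) -> float:
    """Secondary statistic: fraction of total UD mass inside the boundary.

    Integrates density over cells whose centers fall inside the projected
    boundary; distinct from the area-based percent_contained.
    """
    import shapely

    bnd = boundary.projected(projection)
    xs, ys = grid.spec.x_centers(), grid.spec.y_centers()
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    inside = shapely.contains(bnd, pts).reshape(grid.density.shape)
    return float(grid.cell_mass()[inside].sum())
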