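"""Weighted kernel utilization distributions on a fixed working extent.

A utilization distribution (UD) is estimated with a weighted isotropic
Gaussian kernel density estimator evaluated at the centers of a regular
grid over a fixed, conservatively large extent (default 33.7 x 19.3 km)
shared by every UD of a run. The p-level isopleth is the highest-density
region: cells are ranked by density and accumulated until they hold
fraction p of the mass.

Bandwidth is selected by an ad hoc contiguity sweep: starting from a
reference bandwidth, candidates decrease in 250-m steps; the final
bandwidth before the 50% UD polygon becomes non-contiguous is chosen.
When no candidate fragments the polygon, the smallest bandwidth yielding
exactly two polygons is used as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure

logger = logging.getLogger(__name__)

#: working-extent defaults, meters
DEFAULT_EXTENT = (33_700.0, 19_300.0)
DEFAULT_CELL_M = 100.0
SWEEP_STEP_M = 250.0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid over the fixed working extent.

    ``(x0, y0)`` is the lower-left corner; cells are square with side
    ``cell_m``. Cell centers are at ``x0 + (i + 0.5) cell_m``.
    """

    x0: float
    y0: float
    width: float = DEFAULT_EXTENT[0]
    height: float = DEFAULT_EXTENT[1]
    cell_m: float = DEFAULT_CELL_M

    def __post_init__(self) -> None:
        if self.cell_m <= 0:
            raise ValueError("cell size must be > 0")
        if self.nx * self.ny < 4:
            raise ValueError("grid must have at least 4 cells")

    @property
    def nx(self) -> int:
        return int(round(self.width / self.cell_m))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.cell_m))

    @property
    def cell_area(self) -> float:
        return self.cell_m**2

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell_m

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell_m

    @classmethod
    def centered_on(cls, x: float, y: float, width: float = DEFAULT_EXTENT[0],
                    height: float = DEFAULT_EXTENT[1], cell_m: float = DEFAULT_CELL_M) -> "GridSpec":
        return cls(x0=x - width / 2.0, y0=y - height / 2.0,
                   width=width, height=height, cell_m=cell_m)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= self.x0) & (xy[:, 0] <= self.x0 + self.width)
            & (xy[:, 1] >= self.y0) & (xy[:, 1] <= self.y0 + self.height)
        )


@dataclass
class UDGrid:
    """Gridded utilization density (m^-2) integrating to 1 over the grid."""

    spec: GridSpec
    density: np.ndarray  # (ny, nx), row-major over y then x
    bandwidth_m: float

    def cell_mass(self) -> np.ndarray:
        return self.density * self.spec.cell_area

    def to_csv(self, path) -> None:
        """Write as long-form CSV: x,y,density."""
        xs, ys = self.spec.x_centers(), self.spec.y_centers()
        gx, gy = np.meshgrid(xs, ys)
        arr = np.column_stack([gx.ravel(), gy.ravel(), self.density.ravel()])
        np.savetxt(path, arr, delimiter=",", header="x,y,density", comments="")


@dataclass
class UDContour:
    """A p-level isopleth: the smallest cell set holding fraction p of mass."""

    level: float
    spec: GridSpec
    mask: np.ndarray  # (ny, nx) bool, included cells
    n_components: int
    component_mass: np.ndarray  # mass per labeled component, contour-relative
    labels: np.ndarray = field(repr=False, default=None)
    _polygons: MultiPolygon | None = field(default=None, repr=False)

    @property
    def area_m2(self) -> float:
        return float(self.mask.sum()) * self.spec.cell_area

    @property
    def area_km2(self) -> float:
        return self.area_m2 / 1e6

    @property
    def polygons(self) -> MultiPolygon:
        """Cell-boundary polygons of the included region (lazy union of cells)."""
        if self._polygons is None:
            self._polygons = _mask_to_polygons(self.mask, self.spec)
        return self._polygons

    def to_geojson(self, path, projection=None) -> None:
        """Write polygons as GeoJSON (lon/lat if a projection is given)."""
        import json

        geoms = self.polygons
        polys = list(geoms.geoms) if isinstance(geoms, MultiPolygon) else [geoms]

        def ring_coords(ring):
            xy = np.asarray(ring.coords)
            if projection is not None:
                lon, lat = projection.inverse(xy[:, 0], xy[:, 1])
                return [[float(a), float(b)] for a, b in zip(lon, lat)]
            return [[float(a), float(b)] for a, b in xy]

        features = [{
            "type": "Feature",
            "properties": {"level": self.level, "n_components": self.n_components},
            "geometry": {
                "type": "Polygon",
                "coordinates": [ring_coords(p.exterior)] + [ring_coords(r) for r in p.interiors],
            },
        } for p in polys]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def _mask_to_polygons(mask: np.ndarray, spec: GridSpec) -> MultiPolygon:
    """Union of included cell squares as a (Multi)Polygon in grid coordinates."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return MultiPolygon([])
    c = spec.cell_m
    boxes = shapely.box(
        spec.x0 + xs * c, spec.y0 + ys * c,
        spec.x0 + (xs + 1) * c, spec.y0 + (ys + 1) * c,
    )
    merged = unary_union(boxes)
    if isinstance(merged, Polygon):
        merged = MultiPolygon([merged])
    return merged


def weighted_kde(points: np.ndarray, weights: np.ndarray, spec: GridSpec,
                 h: float) -> UDGrid:
    """Weighted Gaussian KDE evaluated at cell centers.

    density(u) = sum_i (w_i / W) (2 pi h^2)^-1 exp(-|u - x_i|^2 / 2 h^2),
    then renormalized to integrate to exactly 1 on the grid. The Gaussian
    kernel is separable, so the grid evaluation is two small matrix
    products rather than an (n_cells x n_points) loop.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    weights = np.asarray(weights, dtype=float).ravel()
    if len(points) == 0:
        raise ValueError("weighted_kde needs at least one point")
    if len(points) != len(weights):
        raise ValueError("points and weights length mismatch")
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    W = weights.sum()
    if W <= 0:
        raise ValueError("weights must not all be zero")

    inside = spec.contains(points)
    if not inside.any():
        raise ValueError("all points fall outside the working extent")
    if not inside.all():
        leak = weights[~inside].sum() / W
        logger.warning("%d point(s) outside the extent; ~%.1f%% of weight may leak",
                       int((~inside).sum()), 100 * leak)

    xs, ys = spec.x_centers(), spec.y_centers()
    # separable kernel: K[c, i] = exp(-(c - x_i)^2 / 2h^2) per axis
    kx = np.exp(-0.5 * ((xs[:, None] - points[None, :, 0]) / h) ** 2)
    ky = np.exp(-0.5 * ((ys[:, None] - points[None, :, 1]) / h) ** 2)
    dens = (ky * (weights / W)[None, :]) @ kx.T  # (ny, nx)
    dens /= 2.0 * np.pi * h**2
    total = dens.sum() * spec.cell_area
    if total <= 0:
        raise ValueError("zero total density on grid (bandwidth too small?)")
    dens = dens / total
    return UDGrid(spec=spec, density=dens, bandwidth_m=float(h))


def ud_contour(grid: UDGrid, p: float) -> UDContour:
    """Highest-density region at probability level p.

    Cells are sorted by density (descending) and accumulated until their
    mass reaches p; connected components of the included set are counted
    with 8-connectivity.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"level must be in (0, 1), got {p}")
    mass = grid.cell_mass().ravel()
    total = mass.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate grid: no mass")
    order = np.argsort(mass, kind="stable")[::-1]
    cum = np.cumsum(mass[order])
    k = int(np.searchsorted(cum, p * total)) + 1
    k = min(k, len(order))
    mask = np.zeros(mass.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(grid.density.shape)

    labels = measure.label(mask, connectivity=2)
    n = int(labels.max())
    comp_mass = np.array([grid.cell_mass()[labels == i + 1].sum() for i in range(n)])
    comp_mass = comp_mass / comp_mass.sum()
    return UDContour(level=p, spec=grid.spec, mask=mask, n_components=n,
                     component_mass=comp_mass, labels=labels)


def is_contiguous(contour: UDContour, sliver_frac: float = 0.01) -> bool:
    """True iff one component remains after dropping sub-1% mass slivers.

    Raster contouring can emit one-cell fragments; components holding less
    than ``sliver_frac`` of the contour's enclosed mass are ignored.
    """
    significant = int(np.sum(contour.component_mass >= sliver_frac))
    return significant <= 1


@dataclass
class BandwidthSelection:
    """Record of the descending 250-m bandwidth sweep."""

    candidates: list[float]
    n_components: list[int]  # raw component count of the 50% UD per candidate
    contiguous: list[bool]
    chosen_h: float
    rule: str  # 'last_contiguous' | 'two_polygon_fallback'
    floor_reached: bool


def silverman_bandwidth(points: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Silverman reference bandwidth for a 2-D isotropic Gaussian KDE.

    Uses the weighted mean of per-axis standard deviations and Kish's
    effective sample size n_eff = (sum w)^2 / sum w^2.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    w = np.asarray(weights, dtype=float).ravel()
    w = w / w.sum()
    n_eff = 1.0 / np.sum(w**2)
    mu = np.average(points, axis=0, weights=w)
    var = np.average((points - mu) ** 2, axis=0, weights=w)
    sigma = float(np.sqrt(var.mean()))
    if sigma <= 0:
        sigma = 1.0
    return sigma * n_eff ** (-1.0 / 6.0)


def select_bandwidth(points: np.ndarray, weights: np.ndarray, spec: GridSpec,
                     h_start: float | None = None, h_min: float = SWEEP_STEP_M,
                     step: float = SWEEP_STEP_M, level: float = 0.5) -> BandwidthSelection:
    """Descending 250-m bandwidth sweep with the contiguity stopping rule.

    From ``h_start`` down to ``h_min`` in ``step`` decrements, the
    ``level`` (default 50%) UD is computed at each candidate. If a first
    non-contiguous candidate h* appears, the previous candidate
    ``h* + step`` is chosen (rule ``last_contiguous``). If every candidate
    stays contiguous, the smallest candidate with exactly two raw
    components is chosen (rule ``two_polygon_fallback``); failing that,
    the floor itself with ``floor_reached`` flagged.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        raise ValueError("bandwidth selection needs at least 2 points")
    if h_start is None:
        ref = silverman_bandwidth(points, weights)
        h_start = max(step * np.ceil(ref / step), h_min + step)
    if h_start <= h_min:
        raise ValueError(f"h_start ({h_start}) must exceed h_min ({h_min})")

    candidates = list(np.arange(h_start, h_min - 1e-9, -step))
    comps: list[int] = []
    contig: list[bool] = []
    chosen_h = None
    rule = None
    floor_reached = False
    for i, h in enumerate(candidates):
        contour = ud_contour(weighted_kde(points, weights, spec, h), level)
        comps.append(contour.n_components)
        ok = is_contiguous(contour)
        contig.append(ok)
        if not ok and chosen_h is None:
            if i == 0:
                # already fragmented at the start: keep sweeping upward is out
                # of contract; choose the start and flag it
                chosen_h = float(h)
                rule = "last_contiguous"
                logger.warning("50%% UD already non-contiguous at h_start=%.0f m", h)
            else:
                chosen_h = float(candidates[i - 1])
                rule = "last_contiguous"
            break
    else:
        floor_reached = True
        two = [h for h, c in zip(candidates, comps) if c == 2]
        if two:
            chosen_h = float(min(two))
            rule = "two_polygon_fallback"
        else:
            chosen_h = float(candidates[-1])
            rule = "two_polygon_fallback"
            logger.warning("sweep reached floor %.0f m with no fragmentation", h_min)

    # truncate records at the stopping point for auditability
    n_rec = len(comps)
    return BandwidthSelection(candidates=[float(h) for h in candidates[:n_rec]],
                              n_components=comps, contiguous=contig,
                              chosen_h=chosen_h, rule=rule, floor_reached=floor_reached)
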