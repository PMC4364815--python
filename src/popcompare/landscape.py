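"""Predictor matrices for isolation-by-distance analysis.

Three kinds of pairwise predictors are built here:

* straight-line (Euclidean) distances from planar UTM coordinates,
* cost-weighted dispersal distances (CWDD): least-cost accumulated distance
  across a habitat-suitability raster, where cells within a buffer of
  suitable features (coastline, major rivers) cost 1 per meter and all other
  cells carry a penalty multiplier,
* Bray–Curtis dissimilarities of site-level climate scalars (annual
  precipitation, isothermality).

The cost-distance computation is Dijkstra on an 8-connected lattice with the
standard cost-distance convention: a step from cell i to cell j costs
``resolution * (c_i + c_j) / 2``, times ``sqrt(2)`` for diagonal steps, so on
a unit-cost raster the result is plain path length in meters.  Unsuitable
habitat is a finite penalty by default (pairs stay connected); an infinite
penalty turns it into a hard barrier and unreachable pairs become NaN.

Rasters use the ESRI ASCII grid dialect (ncols/nrows/xllcorner/yllcorner/
cellsize/NODATA_value header); feature layers are delimited coordinate lists,
one polyline (or point set) per named layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, Point

from .genotype_core import PopulationSite
from .matrices import PairwiseMatrix

__all__ = [
    "CostRaster",
    "HabitatRule",
    "euclidean_matrix",
    "build_cost_raster",
    "least_cost_matrix",
    "bray_curtis_matrix",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_feature_layers",
    "write_feature_layers",
]

_NODATA_DEFAULT = -9999.0


@dataclass(frozen=True)
class CostRaster:
    """A grid of cell traversal-cost multipliers (>= 1) in planar meters.

    ``grid[0, 0]`` is the north-west cell; ``origin`` is the lower-left
    (south-west) corner, matching the ESRI ASCII convention.  ``NaN`` cells
    are nodata.
    """

    origin: tuple[float, float]  # (xllcorner, yllcorner), meters
    resolution: float  # meters per cell
    grid: np.ndarray  # (nrows, ncols) float, NaN = nodata

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if g.ndim != 2:
            raise ValueError("grid must be 2-D")
        valid = g[~np.isnan(g)]
        if len(valid) and (valid < 1).any():
            raise ValueError("cell costs must be >= 1 (unitless multipliers)")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_of(self, easting: float, northing: float) -> tuple[int, int]:
        """Nearest cell center; ties break toward the lower index."""
        nrows, ncols = self.grid.shape
        col = (easting - self.origin[0]) / self.resolution - 0.5
        row_from_bottom = (northing - self.origin[1]) / self.resolution - 0.5
        c = min(max(int(math.floor(col + 0.5 - 1e-12)), 0), ncols - 1)
        rb = min(max(int(math.floor(row_from_bottom + 0.5 - 1e-12)), 0), nrows - 1)
        return nrows - 1 - rb, c

    def contains(self, easting: float, northing: float) -> bool:
        x0, y0 = self.origin
        nrows, ncols = self.grid.shape
        return (x0 <= easting <= x0 + ncols * self.resolution
                and y0 <= northing <= y0 + nrows * self.resolution)


@dataclass(frozen=True)
class HabitatRule:
    """Suitable-habitat definition: named feature layers with buffer radii.

    Cells within ``buffer_km`` of any listed feature cost 1; cells beyond all
    buffers cost ``outside_penalty`` (> 1, possibly ``inf`` for a hard
    barrier).  Species-specific dispersal-corridor rules take this form,
    e.g. a coastal specialist restricted to within 10 km of the coast, or a
    generalist ranging up to 75 km from rivers and coast.
    """

    feature_layers: Mapping[str, Sequence[tuple[float, float]]]
    buffer_km: Mapping[str, float] | float
    outside_penalty: float = 100.0

    def __post_init__(self) -> None:
        if isinstance(self.buffer_km, (int, float)):
            object.__setattr__(
                self, "buffer_km", {k: float(self.buffer_km) for k in self.feature_layers}
            )
        for k, v in self.buffer_km.items():
            if v <= 0:
                raise ValueError(f"buffer for layer {k!r} must be positive")
        if not self.outside_penalty > 1:
            raise ValueError("outside_penalty must exceed 1")


# ---------------------------------------------------------------------------
# Euclidean distances
# ---------------------------------------------------------------------------

def euclidean_matrix(sites: Sequence[PopulationSite]) -> PairwiseMatrix:
    """Straight-line planar distances (meters) between sites."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    for s in sites:
        s.require_coordinates()
    xy = np.array([[s.easting, s.northing] for s in sites])
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    return PairwiseMatrix(tuple(s.id for s in sites), d)


# ---------------------------------------------------------------------------
# Cost rasters
# ---------------------------------------------------------------------------

def build_cost_raster(
    rule: HabitatRule,
    extent: tuple[float, float, float, float],
    resolution: float,
) -> CostRaster:
    """Rasterize a habitat rule: cost 1 within any buffered feature, else the
    outside penalty.

    ``extent`` is (xmin, ymin, xmax, ymax) in meters.  Distance from a cell
    center to a layer is the minimum planar distance to the layer geometry
    (a polyline for 2+ points, a point otherwise).
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty extent")
    min_buffer_m = min(v * 1000.0 for v in rule.buffer_km.values())
    if resolution > min_buffer_m / 2:
        raise ValueError(
            f"resolution {resolution} m exceeds half the smallest buffer "
            f"({min_buffer_m} m); buffers would be unresolvable"
        )
    ncols = int(math.ceil((xmax - xmin) / resolution))
    nrows = int(math.ceil((ymax - ymin) / resolution))
    cols = xmin + (np.arange(ncols) + 0.5) * resolution
    rows = ymax - (np.arange(nrows) + 0.5) * resolution  # row 0 = north
    cx, cy = np.meshgrid(cols, rows)
    centers = np.column_stack([cx.ravel(), cy.ravel()])

    suitable = np.zeros(len(centers), dtype=bool)
    for name, coords in rule.feature_layers.items():
        # vertices sorted lexicographically so the geometry (and hence the
        # raster) is independent of the listing order of the feature file
        pts = sorted(tuple(map(float, c)) for c in coords)
        geom = LineString(pts) if len(pts) >= 2 else Point(pts[0])
        buf = rule.buffer_km[name] * 1000.0
        dists = np.array([geom.distance(Point(p)) for p in centers])
        suitable |= dists <= buf + 1e-9
    grid = np.where(suitable, 1.0, rule.outside_penalty).reshape(nrows, ncols)
    return CostRaster(origin=(xmin, ymin), resolution=resolution, grid=grid)


# ---------------------------------------------------------------------------
# Least-cost distances
# ---------------------------------------------------------------------------

def _lattice_graph(raster: CostRaster) -> coo_matrix:
    g = raster.grid
    nrows, ncols = g.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    rows_i, cols_j, w = [], [], []
    steps = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))]
    for dr, dc, scale in steps:
        r0 = slice(0, nrows - dr)
        r1 = slice(dr, nrows)
        if dc >= 0:
            c0, c1 = slice(0, ncols - dc), slice(dc, ncols)
        else:
            c0, c1 = slice(-dc, ncols), slice(0, ncols + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        cost = raster.resolution * scale * 0.5 * (g[r0, c0].ravel() + g[r1, c1].ravel())
        ok = ~np.isnan(cost) & np.isfinite(cost)
        rows_i.append(a[ok])
        cols_j.append(b[ok])
        w.append(cost[ok])
    n = nrows * ncols
    return coo_matrix(
        (np.concatenate(w), (np.concatenate(rows_i), np.concatenate(cols_j))),
        shape=(n, n),
    )


def least_cost_matrix(
    raster: CostRaster, sites: Sequence[PopulationSite]
) -> PairwiseMatrix:
    """Minimum accumulated cost (cost-weighted meters) between all site pairs.

    Sites snap to the nearest cell center.  A site outside the raster or in a
    nodata cell is an error; pairs separated by an impassable (infinite or
    nodata) barrier come back as NaN with a warning.
    """
    nrows, ncols = raster.shape
    nodes = []
    for s in sites:
        s.require_coordinates()
        if not raster.contains(s.easting, s.northing):
            raise ValueError(f"site {s.id!r} falls outside the raster extent")
        r, c = raster.cell_of(s.easting, s.northing)
        if np.isnan(raster.grid[r, c]):
            raise ValueError(f"site {s.id!r} falls in a nodata cell")
        nodes.append(r * ncols + c)
    graph = _lattice_graph(raster)
    dist = dijkstra(graph, directed=False, indices=nodes)
    k = len(sites)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = dist[i, nodes[j]]
            if not np.isfinite(d):
                warnings.warn(
                    f"no finite-cost path between {sites[i].id!r} and "
                    f"{sites[j].id!r}; pair reported as NA"
                )
                d = np.nan
            out[i, j] = out[j, i] = d
    return PairwiseMatrix(tuple(s.id for s in sites), out)


# ---------------------------------------------------------------------------
# Climate dissimilarity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(
    sites: Sequence[PopulationSite], variable: str
) -> PairwiseMatrix:
    """Bray–Curtis dissimilarity of a site-level climate scalar.

    For scalars this is ``|x - y| / (x + y)`` (0 when both are zero); values
    must be non-negative for the measure to be defined.
    """
    vals = []
    for s in sites:
        if variable not in s.climate:
            raise KeyError(f"site {s.id!r} lacks climate variable {variable!r}")
        v = s.climate[variable]
        if v < 0:
            raise ValueError(
                f"Bray–Curtis undefined for negative values ({variable}={v} "
                f"at {s.id!r})"
            )
        vals.append(v)
    x = np.asarray(vals, dtype=float)
    num = np.abs(x[:, None] - x[None, :])
    den = x[:, None] + x[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(tuple(s.id for s in sites), d)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> CostRaster:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/
    NODATA_value header, rows north to south)."""
    lines = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {req!r}")
    nodata = header.get("nodata_value", _NODATA_DEFAULT)
    data = np.loadtxt(lines[i:].__iter__())
    grid = np.asarray(data, dtype=float).reshape(
        int(header["nrows"]), int(header["ncols"])
    )
    grid = np.where(grid == nodata, np.nan, grid)
    return CostRaster(
        origin=(header["xllcorner"], header["yllcorner"]),
        resolution=header["cellsize"],
        grid=grid,
    )


def write_ascii_grid(raster: CostRaster, path: str | Path) -> None:
    nrows, ncols = raster.shape
    head = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.resolution:.6f}\n"
        f"NODATA_value {_NODATA_DEFAULT:g}\n"
    )
    grid = np.where(np.isnan(raster.grid), _NODATA_DEFAULT, raster.grid)
    body = "\n".join(" ".join(f"{v:g}" for v in row) for row in grid)
    Path(path).write_text(head + body + "\n")


# ---------------------------------------------------------------------------
# Feature-layer I/O (delimited coordinate lists)
# ---------------------------------------------------------------------------

def read_feature_layers(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read feature layers from a delimited file with columns layer,easting,northing."""
    layers: dict[str, list[tuple[float, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.lower().startswith("layer"):
            continue
        parts = [p.strip() for p in line.replace("\t", ",").split(",")]
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected layer,easting,northing")
        layers.setdefault(parts[0], []).append((float(parts[1]), float(parts[2])))
    return layers


def write_feature_layers(
    layers: Mapping[str, Sequence[tuple[float, float]]], path: str | Path
) -> None:
    lines = ["layer,easting,northing"]
    for name, coords in layers.items():
        for x, y in coords:
            lines.append(f"{name},{x:.3f},{y:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
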