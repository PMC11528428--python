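"""Occupied-area estimation from molecular coordinates.

Three estimators delimit the region accessible to the interacting
molecules, all parametrized by the mean first nearest-neighbor distance
mu_NND of the input coordinates:

Delaunay tessellation
    keep triangles with area <= (F_D * mu_NND)^2; the pattern is their
    union and the area the exact sum of accepted triangle areas.
Voronoi tessellation
    keep bounded cells with area <= (F_V * mu_NND)^2 (unbounded boundary
    cells are always rejected); area is the exact sum of accepted cells.
ks-density
    Gaussian kernel density surface with sigma = F_K * mu_NND, normalized
    to unit mass, thresholded at TH = c / (2*pi*sigma^2*N); the pattern is
    the super-threshold raster and the area the pixel count times the
    pixel area.  With c > 1 an isolated molecule is rejected, which is
    what excludes voids and stray localizations.

In two-species analyses the nearest-neighbor scale should be computed
within species (see :func:`species_mean_nnd`): the distance between the
two labels of a bound complex reflects label geometry and localization
noise, not the spatial occupancy scale, and would otherwise drag the
acceptance thresholds toward zero at high affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from numba import njit
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay, Voronoi, cKDTree

from .errors import (
    DataError,
    DegenerateGeometryError,
    ParameterError,
    ResolutionError,
)

NM_PER_UM = 1000.0


def mean_nnd(points: np.ndarray) -> float:
    """Mean distance to the first nearest (distinct) neighbor, in nm."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ParameterError("mean_nnd requires >= 2 points")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    return float(dist[:, 1].mean())


def species_mean_nnd(points: np.ndarray, species: np.ndarray | None) -> float:
    """Count-weighted average of the per-species mean first-NND.

    Falls back to the pooled :func:`mean_nnd` when ``species`` is None or
    has a single label.
    """
    points = np.asarray(points, dtype=float)
    if species is None:
        return mean_nnd(points)
    species = np.asarray(species)
    labels = np.unique(species)
    if labels.size == 1:
        return mean_nnd(points)
    total = 0.0
    n = 0
    for lab in labels:
        sub = points[species == lab]
        if sub.shape[0] < 2:
            continue
        total += mean_nnd(sub) * sub.shape[0]
        n += sub.shape[0]
    if n == 0:
        raise ParameterError("no species has >= 2 points")
    return total / n


@dataclass
class ConfusionStats:
    """Pixel-wise confusion counts of a recovered mask against truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2.0 * self.tp / denom if denom else 0.0


@dataclass
class PatternMask:
    """Rasterized occupied-area estimate.

    ``occupancy[j, i]`` covers the pixel with lower-left corner
    ``(origin_x + i*pixel_nm, origin_y + j*pixel_nm)``.  For the
    tessellation methods ``area_um2`` is the exact sum of accepted
    element areas and the raster is only a rendering; for ks-density the
    raster *is* the estimate.  ``point_membership`` marks which input
    points belong to the pattern under the method's own rule (vertex of
    an accepted triangle / own cell accepted / own pixel occupied).
    """

    origin: tuple[float, float]  # nm
    pixel_nm: float
    occupancy: np.ndarray
    area_um2: float
    method: str
    params: dict = field(default_factory=dict)
    mu_nnd_nm: float = float("nan")
    point_membership: np.ndarray | None = None

    @property
    def raster_area_um2(self) -> float:
        return float(self.occupancy.sum()) * self.pixel_nm**2 / NM_PER_UM**2

    def contains(self, x, y) -> np.ndarray:
        """Occupancy lookup at coordinates (nm); False outside the frame."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        i = np.floor((x - self.origin[0]) / self.pixel_nm).astype(np.int64)
        j = np.floor((y - self.origin[1]) / self.pixel_nm).astype(np.int64)
        ny, nx = self.occupancy.shape
        ok = (i >= 0) & (i < nx) & (j >= 0) & (j < ny)
        out = np.zeros(x.size, dtype=bool)
        out[ok] = self.occupancy[j[ok], i[ok]]
        return out


@njit(cache=True)
def _fill_triangles(tris, x0, y0, px, nx, ny, out):  # pragma: no cover - numba
    for t in range(tris.shape[0]):
        ax, ay = tris[t, 0, 0], tris[t, 0, 1]
        bx, by = tris[t, 1, 0], tris[t, 1, 1]
        cx, cy = tris[t, 2, 0], tris[t, 2, 1]
        d = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
        if d == 0.0:
            continue
        xmin = min(ax, min(bx, cx))
        xmax = max(ax, max(bx, cx))
        ymin = min(ay, min(by, cy))
        ymax = max(ay, max(by, cy))
        i0 = max(int((xmin - x0) / px), 0)
        i1 = min(int((xmax - x0) / px) + 1, nx - 1)
        j0 = max(int((ymin - y0) / px), 0)
        j1 = min(int((ymax - y0) / px) + 1, ny - 1)
        for j in range(j0, j1 + 1):
            pyc = y0 + (j + 0.5) * px
            for i in range(i0, i1 + 1):
                pxc = x0 + (i + 0.5) * px
                w0 = (bx - ax) * (pyc - ay) - (pxc - ax) * (by - ay)
                w1 = (cx - bx) * (pyc - by) - (pxc - bx) * (cy - by)
                w2 = (ax - cx) * (pyc - cy) - (pxc - cx) * (ay - cy)
                if d > 0.0:
                    if w0 >= 0.0 and w1 >= 0.0 and w2 >= 0.0:
                        out[j, i] = True
                else:
                    if w0 <= 0.0 and w1 <= 0.0 and w2 <= 0.0:
                        out[j, i] = True


def _grid(points, bounds, pixel_nm):
    if bounds is None:
        pad = 2.0 * pixel_nm
        bounds = (
            points[:, 0].min() - pad,
            points[:, 1].min() - pad,
            points[:, 0].max() + pad,
            points[:, 1].max() + pad,
        )
    x0, y0, x1, y1 = map(float, bounds)
    nx = max(int(math.ceil((x1 - x0) / pixel_nm)), 1)
    ny = max(int(math.ceil((y1 - y0) / pixel_nm)), 1)
    return (x0, y0), nx, ny


def _triangle_areas(points, simplices):
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    return 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )


def delaunay_pattern(
    points: np.ndarray,
    f_d: float = 3.0,
    mu_nnd_nm: float | None = None,
    pixel_nm: float | None = None,
    bounds: tuple | None = None,
) -> PatternMask:
    """Delaunay-tessellation area: union of triangles with area <= (f_d*mu)^2."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ParameterError("delaunay_pattern requires >= 3 points")
    if f_d <= 0:
        raise ParameterError("f_d must be > 0")
    mu = float(mu_nnd_nm) if mu_nnd_nm is not None else mean_nnd(points)
    try:
        tri = Delaunay(points)
    except Exception as exc:  # qhull raises on degenerate input
        raise DegenerateGeometryError(f"Delaunay triangulation failed: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("all points collinear")
    areas = _triangle_areas(points, tri.simplices)
    accept = areas <= (f_d * mu) ** 2
    area_um2 = float(areas[accept].sum()) / NM_PER_UM**2
    membership = np.zeros(points.shape[0], dtype=bool)
    membership[np.unique(tri.simplices[accept])] = True
    pixel = pixel_nm if pixel_nm is not None else max(mu / 4.0, 1e-3)
    origin, nx, ny = _grid(points, bounds, pixel)
    occ = np.zeros((ny, nx), dtype=bool)
    if accept.any():
        _fill_triangles(
            np.ascontiguousarray(points[tri.simplices[accept]]),
            origin[0],
            origin[1],
            pixel,
            nx,
            ny,
            occ,
        )
    return PatternMask(
        origin=origin,
        pixel_nm=pixel,
        occupancy=occ,
        area_um2=area_um2,
        method="delaunay",
        params={"f_d": f_d},
        mu_nnd_nm=mu,
        point_membership=membership,
    )


def _voronoi_cells(points):
    """Per-point bounded Voronoi cell polygons (None if unbounded)."""
    try:
        vor = Voronoi(points)
    except Exception as exc:
        raise DegenerateGeometryError(f"Voronoi diagram failed: {exc}") from exc
    cells = []
    for p in range(points.shape[0]):
        region = vor.regions[vor.point_region[p]]
        if len(region) < 3 or -1 in region:
            cells.append(None)
            continue
        verts = vor.vertices[region]
        centroid = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - centroid[1], verts[:, 0] - centroid[0]))
        cells.append(verts[order])
    return cells


def _shoelace(verts):
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_pattern(
    points: np.ndarray,
    f_v: float = 3.0,
    mu_nnd_nm: float | None = None,
    pixel_nm: float | None = None,
    bounds: tuple | None = None,
) -> PatternMask:
    """Voronoi-tessellation area: union of bounded cells <= (f_v*mu)^2.

    Unbounded cells (boundary points) are always rejected so the
    estimator never credits area outside the data's support.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 4:
        raise ParameterError("voronoi_pattern requires >= 4 points")
    if f_v <= 0:
        raise ParameterError("f_v must be > 0")
    mu = float(mu_nnd_nm) if mu_nnd_nm is not None else mean_nnd(points)
    cells = _voronoi_cells(points)
    threshold = (f_v * mu) ** 2
    membership = np.zeros(points.shape[0], dtype=bool)
    accepted = []
    area_nm2 = 0.0
    for p, verts in enumerate(cells):
        if verts is None:
            continue
        cell_area = _shoelace(verts)
        if cell_area <= threshold:
            membership[p] = True
            accepted.append(verts)
            area_nm2 += cell_area
    pixel = pixel_nm if pixel_nm is not None else max(mu / 4.0, 1e-3)
    origin, nx, ny = _grid(points, bounds, pixel)
    occ = np.zeros((ny, nx), dtype=bool)
    if accepted:
        # fan-triangulate each convex cell and reuse the triangle rasterizer
        tris = []
        for verts in accepted:
            for k in range(1, verts.shape[0] - 1):
                tris.append((verts[0], verts[k], verts[k + 1]))
        _fill_triangles(
            np.ascontiguousarray(np.array(tris)), origin[0], origin[1], pixel, nx, ny, occ
        )
    return PatternMask(
        origin=origin,
        pixel_nm=pixel,
        occupancy=occ,
        area_um2=area_nm2 / NM_PER_UM**2,
        method="voronoi",
        params={"f_v": f_v},
        mu_nnd_nm=mu,
        point_membership=membership,
    )


def ksdensity_pattern(
    points: np.ndarray,
    f_k: float = 1.0,
    th_constant: float = 1.5,
    pixel_nm: float | None = None,
    mu_nnd_nm: float | None = None,
    bounds: tuple | None = None,
) -> PatternMask:
    """ks-density area: thresholded Gaussian kernel density surface.

    The surface is the normalized KDE (N kernels of mass 1/N, sigma =
    f_k * mu_NND, truncated at 4 sigma); occupancy is density >=
    TH = th_constant / (2*pi*sigma^2*N), i.e. ``th_constant`` times the
    peak height of a single kernel.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 1:
        raise ParameterError("ksdensity_pattern requires >= 1 point")
    if f_k <= 0 or th_constant <= 0:
        raise ParameterError("f_k and th_constant must be > 0")
    mu = float(mu_nnd_nm) if mu_nnd_nm is not None else mean_nnd(points)
    sigma = f_k * mu
    if sigma <= 0:
        raise ParameterError("kernel sigma is zero (coincident points?)")
    pixel = pixel_nm if pixel_nm is not None else min(mu / 4.0, sigma / 3.0)
    if pixel > sigma / 2.0:
        raise ResolutionError(
            f"pixel_nm={pixel:.3g} undersamples the kernel (sigma={sigma:.3g}); "
            "need pixel_nm <= sigma/2"
        )
    origin, nx, ny = _grid(points, bounds, pixel)
    xe = origin[0] + pixel * np.arange(nx + 1)
    ye = origin[1] + pixel * np.arange(ny + 1)
    counts, _, _ = np.histogram2d(points[:, 1], points[:, 0], bins=(ye, xe))
    smoothed = gaussian_filter(counts, sigma=sigma / pixel, mode="constant", truncate=4.0)
    n_total = points.shape[0]
    density = smoothed / (n_total * pixel**2)  # nm^-2, integrates to ~1
    th = th_constant / (2.0 * math.pi * sigma * sigma * n_total)
    occ = density >= th
    mask = PatternMask(
        origin=origin,
        pixel_nm=pixel,
        occupancy=occ,
        area_um2=float(occ.sum()) * pixel**2 / NM_PER_UM**2,
        method="ksdensity",
        params={"f_k": f_k, "th_constant": th_constant},
        mu_nnd_nm=mu,
    )
    mask.point_membership = mask.contains(points[:, 0], points[:, 1])
    return mask


def mask_from_polygon(
    polygon,
    pixel_nm: float,
    bounds: tuple,
    polygon_unit: str = "um",
    shape: tuple | None = None,
) -> PatternMask:
    """Rasterize a (ground-truth) polygon onto a grid as a PatternMask.

    ``shape = (ny, nx)`` pins the raster dimensions (e.g. to match an
    existing mask grid exactly); otherwise they derive from ``bounds``.
    """
    scale = NM_PER_UM if polygon_unit == "um" else 1.0
    origin, nx, ny = _grid(None, bounds, pixel_nm)
    if shape is not None:
        ny, nx = shape
    xc = origin[0] + (np.arange(nx) + 0.5) * pixel_nm
    yc = origin[1] + (np.arange(ny) + 0.5) * pixel_nm
    gx, gy = np.meshgrid(xc / scale, yc / scale)
    occ = shapely.contains_xy(polygon, gx.ravel(), gy.ravel()).reshape(ny, nx)
    return PatternMask(
        origin=origin,
        pixel_nm=pixel_nm,
        occupancy=occ,
        area_um2=float(occ.sum()) * pixel_nm**2 / NM_PER_UM**2,
        method="polygon",
        params={},
    )


def score_pattern(recovered: PatternMask, truth_polygon) -> ConfusionStats:
    """Pixel-wise confusion of a recovered mask against the true polygon.

    The polygon (um coordinates) is rasterized on the recovered mask's
    own grid, so both classifications share the frame by construction.
    """
    ny, nx = recovered.occupancy.shape
    x0, y0 = recovered.origin
    truth = mask_from_polygon(
        truth_polygon,
        recovered.pixel_nm,
        (x0, y0, x0 + nx * recovered.pixel_nm, y0 + ny * recovered.pixel_nm),
        shape=(ny, nx),
    )
    t = truth.occupancy
    r = recovered.occupancy
    if t.shape != r.shape:
        raise ParameterError("raster frames do not match")
    tp = int(np.sum(t & r))
    fp = int(np.sum(~t & r))
    fn = int(np.sum(t & ~r))
    tn = int(np.sum(~t & ~r))
    return ConfusionStats(tp=tp, fp=fp, fn=fn, tn=tn)


_METHODS = {
    "delaunay": delaunay_pattern,
    "voronoi": voronoi_pattern,
    "ksdensity": ksdensity_pattern,
}


def estimate_pattern(points, method: str, factor: float, **kwargs) -> PatternMask:
    """Dispatch to one of the three estimators by name."""
    if method not in _METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if method == "delaunay":
        return delaunay_pattern(points, f_d=factor, **kwargs)
    if method == "voronoi":
        return voronoi_pattern(points, f_v=factor, **kwargs)
    return ksdensity_pattern(points, f_k=factor, **kwargs)


def optimize_expansion_factor(
    points,
    method: str,
    truth_polygon,
    factor_grid,
    **kwargs,
) -> tuple[float, dict]:
    """Pick the expansion factor maximizing pixel-wise F1 against truth.

    Ties are broken toward the smaller factor (the more conservative
    area estimate).  Returns the winner and the per-factor confusion
    statistics.
    """
    factor_grid = list(factor_grid)
    if not factor_grid:
        raise ParameterError("factor_grid must be non-empty")
    scores: dict[float, ConfusionStats] = {}
    for factor in factor_grid:
        mask = estimate_pattern(points, method, factor, **kwargs)
        scores[factor] = score_pattern(mask, truth_polygon)
    best = min(scores, key=lambda f: (-scores[f].f1, f))
    return best, scores
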