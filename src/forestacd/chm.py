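"""Point cloud to canopy height model (CHM).

Implements the processing chain used for low-relief floodplain sites:

1. split the cloud into tiles (``tile_cloud``),
2. drop isolated points (``remove_noise``),
3. label ground vs non-ground returns (``classify_ground``),
4. keep per-cell extremes on a fine grid (``thin_extremes``),
5. grid the thinned points into DEM and DSM rasters (``rasterize``),
6. collapse the DEM to a single planar ground elevation via a low
   percentile with a histogram-peak sanity check (``flat_dem``),
7. subtract that elevation from the DSM (``make_chm``),
8. summarize canopy height over a plot polygon (``plot_canopy_stats``).

The flat-DEM step is the key simplification: on a floodplain with <1 m
of true relief, a low percentile of the (noisy, vegetation-contaminated)
DEM is a more reliable ground elevation than the DEM surface itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
import shapely

from .cloud import GROUND, NOISE, NON_GROUND, PointCloud, merge_clouds
from .raster import GridRaster


# --------------------------------------------------------------------- tiling


def tile_cloud(cloud: PointCloud, tile_size: float) -> list[PointCloud]:
    """Partition a cloud into square tiles covering its bounding box.

    The union of the returned tiles is exactly the input point set;
    points on the max-x/max-y boundary are clipped into the last tile.
    An empty cloud yields an empty list.
    """
    if tile_size <= 0:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    if len(cloud) == 0:
        return []
    xmin, ymin, xmax, ymax = cloud.bounds()
    ntx = max(1, int(np.ceil((xmax - xmin) / tile_size - 1e-12)))
    nty = max(1, int(np.ceil((ymax - ymin) / tile_size - 1e-12)))
    ix = np.clip(((cloud.x - xmin) / tile_size).astype(int), 0, ntx - 1)
    iy = np.clip(((cloud.y - ymin) / tile_size).astype(int), 0, nty - 1)
    tiles = []
    for ty in range(nty):
        for tx in range(ntx):
            mask = (ix == tx) & (iy == ty)
            tiles.append(cloud.select(mask))
    return tiles


# --------------------------------------------------------- isolated-point filter


def remove_noise(
    cloud: PointCloud, cell: float = 1.0, max_neighbors_for_noise: int = 2
) -> PointCloud:
    """Drop isolated points, emulating a 3-D occupancy-grid noise filter.

    A point is noise when the 3x3x3 block of ``cell``-sized voxels centred
    on its own voxel contains ``max_neighbors_for_noise`` or fewer *other*
    points. Noise points are labelled and excluded from the result.
    """
    if cell <= 0:
        raise ValueError(f"cell must be positive, got {cell}")
    if len(cloud) == 0:
        return cloud
    idx = np.floor(cloud.xyz / cell).astype(np.int64)
    idx -= idx.min(axis=0)
    base = np.int64(1) << 20
    keys = (idx[:, 0] * base + idx[:, 1]) * base + idx[:, 2]
    uniq, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
    lookup = dict(zip(uniq.tolist(), counts.tolist()))
    # neighborhood occupancy per unique cell, via 27 shifted lookups
    neigh = np.zeros(len(uniq), dtype=np.int64)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    for dx, dy, dz in offsets:
        shifted = uniq + (np.int64(dx) * base + np.int64(dy)) * base + np.int64(dz)
        neigh += np.array([lookup.get(k, 0) for k in shifted.tolist()], dtype=np.int64)
    n_others = neigh[inverse] - 1  # exclude the point itself
    is_noise = n_others <= max_neighbors_for_noise
    cloud.classification[is_noise] = NOISE
    return cloud.select(~is_noise)


# ------------------------------------------------------------ ground labelling


def classify_ground(
    cloud: PointCloud, grid: float = 2.0, max_ground_offset: float = 0.3
) -> PointCloud:
    """Label every point ground or non-ground.

    A simplified bare-earth filter: the lowest point of each coarse grid
    cell is a ground candidate; a surface is interpolated through the
    candidates (linear inside the convex hull, nearest outside) and every
    point within ``max_ground_offset`` of it is labelled ground.
    This stands in for proprietary LiDAR ground filters; the planar
    flat-DEM step downstream supersedes most of its detail anyway.
    """
    if grid <= 0:
        raise ValueError(f"grid must be positive, got {grid}")
    if len(cloud) == 0:
        raise ValueError("cannot classify an empty cloud")
    xmin, ymin, _, _ = cloud.bounds()
    ix = ((cloud.x - xmin) / grid).astype(int)
    iy = ((cloud.y - ymin) / grid).astype(int)
    keys = ix.astype(np.int64) * (iy.max() + 1) + iy
    order = np.lexsort((cloud.z, keys))
    sorted_keys = keys[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = sorted_keys[1:] != sorted_keys[:-1]
    cand = order[first]  # index of lowest point per occupied cell

    cxy = cloud.xyz[cand, :2]
    cz = cloud.z[cand]
    if len(cand) >= 3 and np.ptp(cxy[:, 0]) > 0 and np.ptp(cxy[:, 1]) > 0:
        lin = LinearNDInterpolator(cxy, cz)
        surf = lin(cloud.x, cloud.y)
        missing = ~np.isfinite(surf)
        if missing.any():
            near = NearestNDInterpolator(cxy, cz)
            surf[missing] = near(cloud.x[missing], cloud.y[missing])
    else:
        surf = np.full(len(cloud), cz.min())
    is_ground = cloud.z - surf <= max_ground_offset
    classification = np.where(is_ground, GROUND, NON_GROUND).astype(np.uint8)
    return PointCloud(cloud.xyz.copy(), classification)


# ----------------------------------------------------------------- thinning


def thin_extremes(cloud: PointCloud, grid: float = 0.05, mode: str = "highest") -> PointCloud:
    """Keep exactly one point per occupied fine-grid cell.

    ``mode='highest'`` keeps the max-z point of each cell (DSM prep),
    ``mode='lowest'`` the min-z point (DEM prep).
    """
    if grid <= 0:
        raise ValueError(f"grid must be positive, got {grid}")
    if mode not in ("lowest", "highest"):
        raise ValueError(f"mode must be 'lowest' or 'highest', got {mode!r}")
    if len(cloud) == 0:
        return cloud
    xmin, ymin, _, _ = cloud.bounds()
    ix = ((cloud.x - xmin) / grid).astype(np.int64)
    iy = ((cloud.y - ymin) / grid).astype(np.int64)
    keys = ix * (iy.max() + 1) + iy
    z = cloud.z if mode == "lowest" else -cloud.z
    order = np.lexsort((z, keys))
    sorted_keys = keys[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = sorted_keys[1:] != sorted_keys[:-1]
    return cloud.select(np.sort(order[first]))


# --------------------------------------------------------------- rasterization


def rasterize(
    cloud: PointCloud,
    resolution: float,
    reducer: str = "max",
    bounds: tuple[float, float, float, float] | None = None,
    fill_max_distance: float = 0.5,
) -> GridRaster:
    """Grid point z-values into a raster.

    Each occupied cell receives the ``reducer`` (min/max/mean) of its
    points' z. Unoccupied cells are filled from their nearest occupied
    cell if that cell lies within ``fill_max_distance`` (metres),
    otherwise left nodata.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if reducer not in ("min", "max", "mean"):
        raise ValueError(f"unknown reducer {reducer!r}")
    if bounds is None:
        if len(cloud) == 0:
            raise ValueError("empty cloud needs explicit bounds")
        bounds = cloud.bounds()
    xmin, ymin, xmax, ymax = bounds
    ncols = max(1, int(np.ceil((xmax - xmin) / resolution - 1e-9)))
    nrows = max(1, int(np.ceil((ymax - ymin) / resolution - 1e-9)))
    values = np.full((nrows, ncols), np.nan)
    if len(cloud) > 0:
        col = np.clip(((cloud.x - xmin) / resolution).astype(int), 0, ncols - 1)
        row = np.clip(
            nrows - 1 - ((cloud.y - ymin) / resolution).astype(int), 0, nrows - 1
        )
        flat = row * ncols + col
        if reducer == "mean":
            acc = np.zeros(nrows * ncols)
            cnt = np.zeros(nrows * ncols)
            np.add.at(acc, flat, cloud.z)
            np.add.at(cnt, flat, 1.0)
            with np.errstate(invalid="ignore"):
                values = (acc / np.where(cnt > 0, cnt, np.nan)).reshape(nrows, ncols)
        else:
            init = np.inf if reducer == "min" else -np.inf
            acc = np.full(nrows * ncols, init)
            op = np.minimum if reducer == "min" else np.maximum
            op.at(acc, flat, cloud.z)
            acc[~np.isfinite(acc)] = np.nan
            values = acc.reshape(nrows, ncols)
    raster = GridRaster(origin=(xmin, ymin), cell_size=resolution, values=values)
    if fill_max_distance > 0:
        raster = _fill_gaps(raster, fill_max_distance)
    return raster


def _fill_gaps(raster: GridRaster, max_distance: float) -> GridRaster:
    """Nearest-neighbor fill of nodata cells within ``max_distance`` metres."""
    values = raster.values
    missing = ~np.isfinite(values)
    if not missing.any() or missing.all():
        return raster
    dist, (ri, ci) = ndimage.distance_transform_edt(missing, return_indices=True)
    filled = values.copy()
    reachable = missing & (dist * raster.cell_size <= max_distance)
    filled[reachable] = values[ri[reachable], ci[reachable]]
    return raster.copy_with(filled)


# ----------------------------------------------------------------- flat DEM


@dataclass
class HistogramCheck:
    """Sanity check that a chosen ground elevation is a modal DEM value."""

    ground_elevation: float
    modal_bin: tuple[float, float]
    bin_width: float
    passed: bool


def flat_dem(
    dem: GridRaster, percentile: float = 15.0, min_bin_width: float = 0.25
) -> tuple[float, HistogramCheck]:
    """Planar ground elevation as a low percentile of the DEM.

    Returns the linear-interpolation percentile of all valid DEM cells
    together with a histogram check: with Freedman-Diaconis bins, the
    check passes when the chosen elevation falls within one bin width of
    the modal bin. On a low-relief site with ample exposed ground, the
    modal DEM elevation should be the floodplain surface, so a chosen
    ground elevation far from the mode signals a bad percentile choice.
    The check targets metre-scale vegetation contamination, so the bin
    width is floored at ``min_bin_width`` (m) to keep it from tripping
    on centimetre-scale measurement noise.
    """
    vals = dem.finite_values()
    if vals.size == 0:
        raise ValueError("DEM has no valid cells")
    ground = float(np.percentile(vals, percentile))
    if np.ptp(vals) == 0:
        check = HistogramCheck(ground, (vals[0], vals[0]), 0.0, True)
        return ground, check
    edges = np.histogram_bin_edges(vals, bins="fd")
    if len(edges) < 2 or (edges[1] - edges[0]) < min_bin_width:
        lo, hi = vals.min(), vals.max()
        nbins = max(1, int(np.ceil((hi - lo) / min_bin_width)))
        edges = np.linspace(lo, hi, nbins + 1)
    counts, edges = np.histogram(vals, bins=edges)
    k = int(np.argmax(counts))
    lo, hi = float(edges[k]), float(edges[k + 1])
    width = hi - lo
    passed = (lo - width) <= ground <= (hi + width)
    return ground, HistogramCheck(ground, (lo, hi), width, passed)


def make_chm(
    dsm: GridRaster, ground_elevation: float, clamp_negative: bool = True
) -> GridRaster:
    """CHM = DSM minus a planar ground elevation; nodata propagates."""
    values = dsm.values - ground_elevation
    if clamp_negative:
        values = np.where(np.isfinite(values), np.maximum(values, 0.0), np.nan)
    return dsm.copy_with(values)


# ------------------------------------------------------------- plot statistics


@dataclass
class PlotCanopyStats:
    """Canopy-height summary over the CHM cells inside a plot polygon."""

    mean_tch: float
    sd: float
    median: float
    min: float
    max: float
    n_cells: int


def plot_canopy_stats(chm: GridRaster, plot: shapely.Polygon) -> PlotCanopyStats:
    """Summarize CHM cells whose centers fall inside (or on) the polygon.

    ``mean_tch`` is the plot's mean top-of-canopy height, the single
    input metric of the plot-aggregate carbon equations.
    """
    if not isinstance(plot, shapely.Polygon) or plot.area <= 0:
        raise ValueError("plot must be a polygon with positive area")
    if not plot.is_simple:
        raise ValueError("plot polygon must be simple (non-self-intersecting)")
    xs, ys = chm.cell_centers()
    inside = shapely.intersects_xy(plot, xs.ravel(), ys.ravel()).reshape(xs.shape)
    vals = chm.values[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid CHM cells inside the plot")
    return PlotCanopyStats(
        mean_tch=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        n_cells=int(vals.size),
    )


# ------------------------------------------------------------ full chain


@dataclass
class ChmResult:
    """All intermediates of the cloud-to-CHM chain."""

    dem: GridRaster
    dsm: GridRaster
    chm: GridRaster
    ground_elevation: float
    histogram_check: HistogramCheck


def build_chm(
    cloud: PointCloud,
    resolution: float = 0.1,
    thin_grid: float = 0.05,
    flat_dem_percentile: float = 15.0,
    tile_size: float = 50.0,
    noise_cell: float = 1.0,
    noise_max_neighbors: int = 2,
    ground_grid: float = 2.0,
    ground_offset: float = 0.3,
    clamp_negative: bool = True,
    fill_max_distance: float = 0.5,
    swap_surfaces: bool = False,
) -> ChmResult:
    """Run the full cloud-to-CHM chain with one call.

    By default the DEM is built from lowest-thinned ground points and
    the DSM from highest-thinned points (bare earth below, canopy
    surface above). ``swap_surfaces=True`` selects the reverse
    assignment for comparison with workflows that state it the other
    way around.
    """
    tiles = tile_cloud(cloud, tile_size)
    tiles = [remove_noise(t, noise_cell, noise_max_neighbors) for t in tiles if len(t)]
    cleaned = merge_clouds(tiles)
    if len(cleaned) == 0:
        raise ValueError("no points survive noise removal")
    labelled = classify_ground(cleaned, ground_grid, ground_offset)
    bounds = labelled.bounds()

    dem_mode, dsm_mode = ("lowest", "highest") if not swap_surfaces else ("highest", "lowest")
    ground_pts = labelled.where_class(GROUND)
    if len(ground_pts) == 0:
        ground_pts = labelled  # pathological cover: fall back to all points
    dem_pts = thin_extremes(ground_pts, thin_grid, dem_mode)
    dsm_pts = thin_extremes(labelled, thin_grid, dsm_mode)
    dem_reducer = "min" if dem_mode == "lowest" else "max"
    dsm_reducer = "max" if dsm_mode == "highest" else "min"
    dem = rasterize(dem_pts, resolution, dem_reducer, bounds, fill_max_distance)
    dsm = rasterize(dsm_pts, resolution, dsm_reducer, bounds, fill_max_distance)
    ground, check = flat_dem(dem, flat_dem_percentile)
    chm = make_chm(dsm, ground, clamp_negative)
    return ChmResult(dem=dem, dsm=dsm, chm=chm, ground_elevation=ground, histogram_check=check)
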