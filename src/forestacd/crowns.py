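"""Tree-top detection and crown delineation on a CHM.

Tree tops are strict local maxima of the (optionally smoothed) canopy
height model above a height threshold; crowns are grown outward from
each top with a Dalponte-style region-growing rule: a neighboring cell
joins a crown while it is tall enough relative both to the top and to
the crown's running mean height, and close enough to the top. Taller
tops claim contested cells first, so segments are always disjoint.

Because field inventories often record no stem coordinates, validation
against them is distributional: detected crown-height summaries are
compared against the field height list without any one-to-one matching.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import GridRaster


def smooth_chm(chm: GridRaster, window: int = 3) -> GridRaster:
    """Mean-filter the CHM with an odd square window; nodata is excluded
    from each local mean and stays nodata. ``window=1`` is the identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    if window == 1:
        return chm.copy_with(chm.values.copy())
    finite = np.isfinite(chm.values)
    filled = np.where(finite, chm.values, 0.0)
    ssum = ndimage.uniform_filter(filled, size=window, mode="constant", cval=0.0)
    scnt = ndimage.uniform_filter(finite.astype(float), size=window, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(finite & (scnt > 0), ssum / scnt, np.nan)
    return chm.copy_with(out)


@dataclass
class TreeTop:
    """A detected apex: cell-center world coordinates and CHM height."""

    x: float
    y: float
    height: float
    row: int
    col: int


def detect_tree_tops(
    chm: GridRaster, min_height: float = 3.0, min_distance: int = 5
) -> list[TreeTop]:
    """Find tree tops as local maxima of the CHM.

    A cell is a candidate when it attains the maximum of its
    ``(2*min_distance+1)**2`` neighborhood and its height is at least
    ``min_height``. Equal-height ties are resolved in row-major order:
    the first occurrence wins and later tied candidates within
    ``min_distance`` (Chebyshev, in cells) are suppressed.
    """
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    vals = np.where(np.isfinite(chm.values), chm.values, -np.inf)
    size = 2 * min_distance + 1
    local_max = ndimage.maximum_filter(vals, size=size, mode="constant", cval=-np.inf)
    cand = np.argwhere((vals == local_max) & (vals >= min_height) & np.isfinite(chm.values))
    tops: list[TreeTop] = []
    for row, col in cand:  # argwhere is already row-major
        if any(
            max(abs(row - t.row), abs(col - t.col)) <= min_distance for t in tops
        ):
            continue
        x, y = chm.cell_center(row, col)
        tops.append(TreeTop(x=x, y=y, height=float(chm.values[row, col]), row=int(row), col=int(col)))
    return tops


@dataclass
class CrownSegment:
    """A delineated crown: its top plus the 4-connected cell set."""

    top: TreeTop
    cells: set[tuple[int, int]] = field(repr=False)
    max_height: float = 0.0
    area: float = 0.0


def grow_crowns(
    chm: GridRaster,
    tops: list[TreeTop],
    seed_fraction: float = 0.45,
    crown_fraction: float = 0.55,
    max_radius: float = 10.0,
) -> list[CrownSegment]:
    """Region-grow a crown around each top.

    A 4-connected neighbor cell is added while its height is

    * greater than ``seed_fraction`` times the top height,
    * greater than ``crown_fraction`` times the crown's current mean
      height,
    * no taller than the top itself, and
    * within ``max_radius`` metres of the top's cell center.

    Tops are processed in descending height order (row-major on ties) and
    each cell belongs to at most one crown, so taller trees win contested
    cells and the returned segments are pairwise disjoint.
    """
    if not 0 < seed_fraction <= 1 or not 0 < crown_fraction <= 1:
        raise ValueError("seed_fraction and crown_fraction must be in (0, 1]")
    claimed = np.full(chm.values.shape, -1, dtype=int)
    # every apex cell is reserved up front so no crown can swallow another's top
    for i, t in enumerate(tops):
        claimed[t.row, t.col] = i
    order = sorted(range(len(tops)), key=lambda i: (-tops[i].height, tops[i].row, tops[i].col))
    segments: dict[int, CrownSegment] = {}
    cell_area = chm.cell_size**2
    for idx in order:
        top = tops[idx]
        cells = {(top.row, top.col)}
        total = float(chm.values[top.row, top.col])
        queue = deque([(top.row, top.col)])
        while queue:
            r, c = queue.popleft()
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < chm.nrows and 0 <= nc < chm.ncols):
                    continue
                if claimed[nr, nc] != -1:
                    continue
                h = chm.values[nr, nc]
                if not np.isfinite(h):
                    continue
                mean_h = total / len(cells)
                if h <= seed_fraction * top.height or h <= crown_fraction * mean_h:
                    continue
                if h > top.height:
                    continue
                cx, cy = chm.cell_center(nr, nc)
                if np.hypot(cx - top.x, cy - top.y) > max_radius:
                    continue
                claimed[nr, nc] = idx
                cells.add((nr, nc))
                total += float(h)
                queue.append((nr, nc))
        segments[idx] = CrownSegment(
            top=top,
            cells=cells,
            max_height=float(max(chm.values[rc] for rc in cells)),
            area=len(cells) * cell_area,
        )
    return [segments[i] for i in sorted(segments)]


@dataclass
class HeightComparison:
    """Distributional comparison of detected crown heights vs field heights."""

    n_detected: int
    n_field: int
    detected_mean: float
    detected_median: float
    field_mean: float
    field_median: float


def compare_heights(
    crowns: list[CrownSegment],
    field_heights: np.ndarray | list[float],
    min_height: float = 3.0,
) -> HeightComparison:
    """Summary statistics of crown max-heights (>= ``min_height``) against
    a field height list. No pairing is attempted: without stem
    geolocations only the two distributions are comparable."""
    det = np.array([c.max_height for c in crowns if c.max_height >= min_height])
    fld = np.asarray(field_heights, dtype=float)

    def _stat(a: np.ndarray, f) -> float:
        return float(f(a)) if a.size else float("nan")

    return HeightComparison(
        n_detected=int(det.size),
        n_field=int(fld.size),
        detected_mean=_stat(det, np.mean),
        detected_median=_stat(det, np.median),
        field_mean=_stat(fld, np.mean),
        field_median=_stat(fld, np.median),
    )


def crowns_to_label_raster(chm: GridRaster, crowns: list[CrownSegment]) -> GridRaster:
    """Integer label mask of the segments (1-based; 0 = unassigned)."""
    labels = np.zeros(chm.values.shape)
    for i, seg in enumerate(crowns, start=1):
        for r, c in seg.cells:
            labels[r, c] = i
    return chm.copy_with(labels)
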