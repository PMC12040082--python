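"""Synthetic forest scenes with known ground truth.

The generator emulates the kind of site the CHM pipeline targets: a
seasonally flooded floodplain with essentially flat ground (<1 m relief,
modelled here as exactly constant), a sparse stand of small trees
(heights of a few to ~20 m), crowns a few metres across, and large
stretches of bare ground. Rendering mimics a photogrammetric surface
reconstruction: only the *top* surface is sampled (one return per
ground position, no canopy penetration), bare ground is sampled
patchily, and every height carries Gaussian vertical noise.

Every downstream stage — ground classification, rasterization, flat-DEM
normalization, crown detection, the allometry arms — can therefore be
tested against analytic truth without any field data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import PointCloud


@dataclass
class TreeTruth:
    """Ground truth for one tree: position, crown geometry, stem metrics."""

    x: float
    y: float
    height: float  # m, apex above ground
    crown_radius: float  # m
    crown_shape: str = "paraboloid"  # or "cone"
    dbh: float = 0.0  # cm
    wood_density: float = 0.54  # g cm^-3

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("tree height must be >= 0")
        if self.crown_radius <= 0:
            raise ValueError("crown_radius must be > 0")
        if self.crown_shape not in ("paraboloid", "cone"):
            raise ValueError(f"unknown crown_shape {self.crown_shape!r}")

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Crown surface height above ground at (x, y); 0 outside the crown."""
        r = np.hypot(np.asarray(x) - self.x, np.asarray(y) - self.y)
        frac = np.clip(r / self.crown_radius, 0.0, 1.0)
        if self.crown_shape == "paraboloid":
            return self.height * (1.0 - frac**2)
        return self.height * (1.0 - frac)


@dataclass
class SceneSpec:
    """A parametric forest scene: flat ground plus a list of trees."""

    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax (m)
    ground_elevation: float
    trees: list[TreeTruth] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"extent must have positive area, got {self.extent}")
        for t in self.trees:
            if not (xmin <= t.x <= xmax and ymin <= t.y <= ymax):
                raise ValueError(f"tree at ({t.x}, {t.y}) outside extent {self.extent}")

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin)

    def canopy_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Analytic top-surface height above ground (max over crowns, 0 bare)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h = np.zeros(np.broadcast(x, y).shape)
        for t in self.trees:
            h = np.maximum(h, t.surface(x, y))
        return h

    def true_mean_tch(self, resolution: float = 0.1) -> float:
        """Ground-truth mean top-of-canopy height on a regular grid.

        Averages the analytic canopy surface at cell centers over the
        whole extent — the recovery target for the CHM pipeline's
        plot-mean TCH.
        """
        xmin, ymin, xmax, ymax = self.extent
        xs = np.arange(xmin + resolution / 2, xmax, resolution)
        ys = np.arange(ymin + resolution / 2, ymax, resolution)
        gx, gy = np.meshgrid(xs, ys)
        return float(self.canopy_height(gx, gy).mean())

    # ------------------------------------------------------------------ I/O

    def to_json(self, path: str | Path) -> None:
        payload = {
            "extent": list(self.extent),
            "ground_elevation": self.ground_elevation,
            "seed": self.seed,
            "trees": [asdict(t) for t in self.trees],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            extent=tuple(payload["extent"]),
            ground_elevation=payload["ground_elevation"],
            seed=payload.get("seed"),
            trees=[TreeTruth(**t) for t in payload["trees"]],
        )


# ----------------------------------------------------------------- generation

#: Height-diameter link used for truth: H = HD_A * DBH ** HD_B (H in m, DBH
#: in cm). Only monotone invertibility matters; the coefficients are a
#: plausible small-tree shape, not a fitted site allometry.
HD_A = 3.0
HD_B = 0.5


def dbh_from_height(height: float | np.ndarray, a: float = HD_A, b: float = HD_B):
    """Invert the H = a * DBH^b link to get DBH (cm) from height (m)."""
    return (np.asarray(height) / a) ** (1.0 / b)


def height_from_dbh(dbh: float | np.ndarray, a: float = HD_A, b: float = HD_B):
    return a * np.asarray(dbh) ** b


def generate_scene(
    extent: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0),
    n_trees: int = 24,
    height_range: tuple[float, float] = (3.0, 19.0),
    crown_radius_range: tuple[float, float] = (1.5, 3.0),
    ground_elevation: float = 10.0,
    crown_shape: str = "paraboloid",
    min_spacing: float | None = None,
    wd_mean: float = 0.54,
    wd_sd: float = 0.11,
    seed: int | None = None,
) -> SceneSpec:
    """Draw a reproducible random scene.

    Tree heights are uniform on ``height_range`` (default 3-19 m, the
    stature of a degraded floodplain stand of ~24 stems), crown radii
    uniform on ``crown_radius_range``, positions uniform inside the
    extent with a crown-radius margin. ``min_spacing`` enforces a
    minimum distance between stems by rejection sampling, for scenes
    where each apex must be an isolated local maximum. DBH is derived
    from height through the invertible H = a * DBH^b link and per-tree
    wood density is drawn from a truncated normal prior.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"extent must have positive area, got {extent}")
    if n_trees < 0:
        raise ValueError("n_trees must be >= 0")
    rng = np.random.default_rng(seed)
    trees: list[TreeTruth] = []
    positions: list[tuple[float, float]] = []
    max_tries = 10000
    for _ in range(n_trees):
        height = float(rng.uniform(*height_range))
        radius = float(rng.uniform(*crown_radius_range))
        mx = min(radius, (xmax - xmin) / 2)
        my = min(radius, (ymax - ymin) / 2)
        for _try in range(max_tries):
            x = float(rng.uniform(xmin + mx, xmax - mx))
            y = float(rng.uniform(ymin + my, ymax - my))
            if min_spacing is None or all(
                np.hypot(x - px, y - py) >= min_spacing for px, py in positions
            ):
                break
        else:
            raise RuntimeError(
                f"could not place {n_trees} trees with min_spacing={min_spacing}"
            )
        positions.append((x, y))
        wd = float(np.clip(rng.normal(wd_mean, wd_sd), 0.1, None))
        trees.append(
            TreeTruth(
                x=x,
                y=y,
                height=height,
                crown_radius=radius,
                crown_shape=crown_shape,
                dbh=float(dbh_from_height(height)),
                wood_density=wd,
            )
        )
    return SceneSpec(extent=extent, ground_elevation=ground_elevation, trees=trees, seed=seed)


# ------------------------------------------------------------------ rendering


def render_point_cloud(
    scene: SceneSpec,
    point_density: float = 50.0,
    ground_fraction: float = 0.8,
    vertical_noise_sd: float = 0.05,
    seed: int | None = None,
) -> PointCloud:
    """Sample the scene's top surface like a photogrammetric point cloud.

    Points sit on a jittered grid with spacing ``1/sqrt(point_density)``
    (deterministic counts under a fixed seed). A sample over a crown
    returns the crown surface; a sample over bare ground is kept with
    probability ``ground_fraction`` (texture-poor ground reconstructs
    patchily) and ground beneath crowns is never seen at all — the
    optical reconstruction has no canopy penetration. Every z carries
    ``Normal(0, vertical_noise_sd)`` noise. Classification codes are
    left unset; labelling is the pipeline's job.
    """
    if point_density <= 0:
        raise ValueError("point_density must be > 0")
    if not 0.0 <= ground_fraction <= 1.0:
        raise ValueError("ground_fraction must be in [0, 1]")
    if vertical_noise_sd < 0:
        raise ValueError("vertical_noise_sd must be >= 0")
    xmin, ymin, xmax, ymax = scene.extent
    rng = np.random.default_rng(seed)
    spacing = 1.0 / np.sqrt(point_density)
    xs = np.arange(xmin, xmax, spacing)
    ys = np.arange(ymin, ymax, spacing)
    gx, gy = np.meshgrid(xs, ys)
    gx = gx.ravel() + rng.uniform(0, spacing, gx.size)
    gy = gy.ravel() + rng.uniform(0, spacing, gy.size)
    keep_extent = (gx < xmax) & (gy < ymax)
    gx, gy = gx[keep_extent], gy[keep_extent]
    h = scene.canopy_height(gx, gy)
    on_canopy = h > 0
    keep = on_canopy | (rng.random(gx.size) < ground_fraction)
    gx, gy, h = gx[keep], gy[keep], h[keep]
    z = scene.ground_elevation + h
    if vertical_noise_sd > 0:
        z = z + rng.normal(0.0, vertical_noise_sd, z.size)
    return PointCloud(np.column_stack([gx, gy, z]))


# ------------------------------------------------------------ field inventory


def generate_field_inventory(
    scene: SceneSpec,
    h_error_sd: float = 0.0,
    dbh_error_rel: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate a clinometer-and-tape tree inventory of the scene.

    Returns one record per tree with measurement noise on height
    (additive, SD ``h_error_sd`` m) and DBH (multiplicative, relative SD
    ``dbh_error_rel``). Wood density is deliberately omitted: field
    crews without species identifications cannot look it up, which is
    why the carbon arm treats WD as a prior distribution instead.
    Columns: ``tree_id, dbh_cm, height_m``.
    """
    if h_error_sd < 0 or dbh_error_rel < 0:
        raise ValueError("error parameters must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, t in enumerate(scene.trees):
        h = t.height + (rng.normal(0, h_error_sd) if h_error_sd > 0 else 0.0)
        d = t.dbh * (1 + (rng.normal(0, dbh_error_rel) if dbh_error_rel > 0 else 0.0))
        rows.append(
            {
                "tree_id": i + 1,
                "dbh_cm": max(d, 0.01 * t.dbh),
                "height_m": max(h, 0.01 * t.height),
            }
        )
    return pd.DataFrame(rows, columns=["tree_id", "dbh_cm", "height_m"])
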