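"""Point-cloud container and text I/O.

Photogrammetric point clouds are held as a flat array of (x, y, z) in a
projected metric CRS plus a per-point classification code. Codes follow
the LAS convention for the classes this pipeline uses:

====  ==============
code  meaning
====  ==============
0     unclassified
2     ground
5     non-ground (vegetation)
7     noise
====  ==============

Clouds are read and written as whitespace- or comma-delimited XYZ text
(``x y z [class]`` per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

UNCLASSIFIED = 0
GROUND = 2
NON_GROUND = 5
NOISE = 7


@dataclass
class PointCloud:
    """Points (n, 3) in metres plus per-point class codes (n,)."""

    xyz: np.ndarray = field(repr=False)
    classification: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.classification is None:
            self.classification = np.full(len(self.xyz), UNCLASSIFIED, dtype=np.uint8)
        else:
            self.classification = np.asarray(self.classification, dtype=np.uint8)
            if self.classification.shape != (len(self.xyz),):
                raise ValueError("classification must have one code per point")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def bounds(self) -> tuple[float, float, float, float]:
        if len(self) == 0:
            raise ValueError("empty cloud has no bounds")
        return (self.x.min(), self.y.min(), self.x.max(), self.y.max())

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz[mask], self.classification[mask])

    def where_class(self, *codes: int) -> "PointCloud":
        return self.select(np.isin(self.classification, codes))

    # ------------------------------------------------------------------ I/O

    def write_xyz(self, path: str | Path, with_class: bool = True) -> None:
        if with_class:
            data = np.column_stack([self.xyz, self.classification])
            np.savetxt(path, data, fmt=["%.4f", "%.4f", "%.4f", "%d"])
        else:
            np.savetxt(path, self.xyz, fmt="%.4f")

    @classmethod
    def read_xyz(cls, path: str | Path) -> "PointCloud":
        """Read whitespace- or comma-delimited ``x y z [class]`` text."""
        with open(path) as fh:
            text = fh.read()
        delimiter = "," if "," in text.splitlines()[0] else None
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        if data.size == 0:
            return cls(np.empty((0, 3)))
        if data.shape[1] == 4:
            return cls(data[:, :3], data[:, 3].astype(np.uint8))
        return cls(data[:, :3])


def merge_clouds(clouds: list[PointCloud]) -> PointCloud:
    """Concatenate clouds (inverse of tiling)."""
    if not clouds:
        return PointCloud(np.empty((0, 3)))
    return PointCloud(
        np.vstack([c.xyz for c in clouds]),
        np.concatenate([c.classification for c in clouds]),
    )
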