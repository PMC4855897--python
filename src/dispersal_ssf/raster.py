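"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Grids are square-celled, axis-aligned, in one projected planar frame
(metres).  Rows of ``data`` increase with *y* (origin at the lower-left
corner), which is the transpose-free convention for simulation code; the
ESRI ASCII writer flips rows so files follow the usual top-down layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "OutOfExtentError"]


class OutOfExtentError(ValueError):
    """A query point fell outside the raster extent."""


@dataclass
class RasterGrid:
    data: np.ndarray  # (nrows, ncols); row i spans y0 + [i, i+1) * cell
    x0: float
    y0: float
    cell: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        nr, nc = self.data.shape
        return (self.x0, self.y0, self.x0 + nc * self.cell, self.y0 + nr * self.cell)

    def in_extent(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def _indices(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x, float) - self.x0) / self.cell).astype(int)
        row = np.floor((np.asarray(y, float) - self.y0) / self.cell).astype(int)
        return row, col

    def sample(self, x, y):
        """Nearest-cell values at points; raises on out-of-extent points."""
        inside = self.in_extent(x, y)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside)).ravel()
            xs = np.atleast_1d(np.asarray(x, float))
            ys = np.atleast_1d(np.asarray(y, float))
            raise OutOfExtentError(
                f"point index {bad[0]} at ({xs[bad[0]]:.1f}, {ys[bad[0]]:.1f}) "
                f"is outside extent {self.extent}"
            )
        row, col = self._indices(x, y)
        return self.data[row, col]

    def write_ascii(self, path: str | Path) -> None:
        nr, nc = self.data.shape
        header = (
            f"ncols {nc}\nnrows {nr}\nxllcorner {self.x0}\nyllcorner {self.y0}\n"
            f"cellsize {self.cell}\nNODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data[::-1], fmt="%.6g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            body = np.loadtxt(fh)
        body = np.atleast_2d(body)
        return cls(body[::-1].copy(), meta["xllcorner"], meta["yllcorner"], meta["cellsize"])
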