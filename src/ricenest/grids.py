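"""Core planar containers: rasters, class schemes, point patterns, plot samples.

All spatial objects live on a planar metric coordinate system (metres).
Rasters are stored north-up: row 0 is the northernmost row, and the grid
``origin`` is the (x, y) of the *lower-left* corner of the raster extent.
The centre of cell (row, col) is therefore::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y + (nrows - row - 0.5) * cell_size
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Grid",
    "ClassScheme",
    "DEFAULT_SCHEME",
    "PointPattern",
    "PlotSample",
    "NODATA_CODE",
]

#: sentinel for missing cells in categorical (uint8-style) grids
NODATA_CODE = 255


@dataclass
class Grid:
    """A single-band raster on a square-celled planar grid.

    Parameters
    ----------
    values
        2-D array, either continuous (float) or category codes (int).
    cell_size
        Edge length of a cell in metres. Cells are square.
    origin
        (x, y) of the lower-left corner of the raster extent, in metres.
    nodata
        Sentinel for missing cells, or ``None`` if the grid is complete.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def window(self) -> tuple[float, float, float, float]:
        """Raster extent as (xmin, ymin, xmax, ymax) in metres."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, each shaped like values."""
        x0, y0 = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.nrows - rows - 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = self.nrows - 1 - int(np.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (self.nrows - row - 0.5) * self.cell_size)

    def like(self, values: np.ndarray, nodata: float | int | None = None) -> "Grid":
        """A new grid with the same geometry carrying ``values``."""
        return Grid(values, self.cell_size, self.origin, nodata)


#: the seven land-cover strata, in fixed run order
DEFAULT_CLASS_NAMES = (
    "winter_flooded_rice",
    "winter_dry_rice",
    "rain_fed",
    "open_water",
    "forest",
    "shrub_grass",
    "other",
)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered land-cover class list; codes are positions in the list."""

    names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("class names must be distinct")
        if len(self.names) != 7:
            raise ValueError(f"scheme must have exactly 7 classes, got {len(self.names)}")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def code(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}") from None

    def validate_codes(self, values: np.ndarray, nodata: int | None = NODATA_CODE) -> None:
        v = np.asarray(values)
        ok = (v >= 0) & (v < self.n_classes)
        if nodata is not None:
            ok |= v == nodata
        if not ok.all():
            bad = np.unique(v[~ok])
            raise ValueError(f"categorical grid contains undeclared codes {bad.tolist()}")


DEFAULT_SCHEME = ClassScheme()


@dataclass
class PointPattern:
    """Planar points with a rectangular observation window.

    Every point must lie strictly inside the window; the window must have
    positive area. Duplicate points are refused unless ``allow_duplicates``.
    """

    points: np.ndarray
    window: tuple[float, float, float, float]
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
        self.points = pts
        xmin, ymin, xmax, ymax = self.window
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"window must have positive area, got {self.window}")
        if pts.shape[0]:
            inside = (pts[:, 0] > xmin) & (pts[:, 0] < xmax) & (pts[:, 1] > ymin) & (pts[:, 1] < ymax)
            if not inside.all():
                raise ValueError(f"{int((~inside).sum())} point(s) outside the window")
            if not self.allow_duplicates and len(np.unique(pts, axis=0)) != len(pts):
                raise ValueError("duplicate points present; pass allow_duplicates=True to keep them")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)


@dataclass
class PlotSample:
    """Stratified ground-truth plots with a 50/50 train/test split."""

    x: np.ndarray
    y: np.ndarray
    true_class: np.ndarray  # integer class codes
    split: np.ndarray  # "train" | "test" per plot
    is_subset: bool = False  # subsets of a full sample skip the equal-halves check

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "true_class", "split"):
            if len(getattr(self, name)) != n:
                raise ValueError("plot sample columns must share length")
        n_train = int(np.sum(self.split == "train"))
        n_test = int(np.sum(self.split == "test"))
        if n_train + n_test != n:
            raise ValueError("split labels must be 'train' or 'test'")
        if not self.is_subset and n % 2 == 0 and n_train != n_test:
            raise ValueError(f"even total must split into equal halves, got {n_train}/{n_test}")

    @property
    def n(self) -> int:
        return len(self.x)

    def half(self, which: str) -> "PlotSample":
        m = self.split == which
        return PlotSample(self.x[m], self.y[m], self.true_class[m], self.split[m], is_subset=True)


def as_point_array(points: Sequence) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    return pts
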