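"""Categorical evidence layers derived from a DEM.

Two layers feed the Bayesian post-classification step: terrain position
(five classes, gully through ridge, from a neighbourhood elevation
percentile) and binned elevation. Terrain position is a rank statistic, so
it is invariant under any strictly monotone transform of the elevation
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import Grid, NODATA_CODE

__all__ = [
    "EvidenceLayer",
    "TerrainScheme",
    "DEFAULT_TERRAIN_SCHEME",
    "classify_terrain_position",
    "classify_elevation",
]


@dataclass
class EvidenceLayer:
    """A named categorical grid with an ordered code→label map."""

    name: str
    grid: Grid
    categories: dict[int, str]

    def __post_init__(self) -> None:
        v = self.grid.values
        valid = self.grid.valid_mask()
        declared = np.isin(v, list(self.categories))
        if not (declared | ~valid).all():
            bad = np.unique(v[valid & ~declared])
            raise ValueError(f"evidence layer {self.name!r} carries undeclared codes {bad.tolist()}")


TERRAIN_LABELS = ("gully", "lower_mid_slope", "mid_slope", "upper_mid_slope", "ridge")


@dataclass(frozen=True)
class TerrainScheme:
    """Five terrain-position classes cut from a percentile in (0, 1).

    Default breaks 0.10/0.35/0.65/0.90 make gully and ridge rare and
    mid-slope common: a cell at the p-th percentile of its neighbourhood
    falls in the class whose break interval contains p.
    """

    breaks: tuple[float, float, float, float] = (0.10, 0.35, 0.65, 0.90)
    labels: tuple[str, ...] = TERRAIN_LABELS

    def __post_init__(self) -> None:
        b = self.breaks
        if len(b) != 4 or any(not 0 < x < 1 for x in b) or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError(f"breaks must be 4 strictly increasing values in (0,1), got {b}")
        if len(self.labels) != 5:
            raise ValueError("terrain scheme needs exactly five labels")


DEFAULT_TERRAIN_SCHEME = TerrainScheme()


def _disk_offsets(radius_cells: int) -> list[tuple[int, int]]:
    r2 = radius_cells * radius_cells
    return [
        (dr, dc)
        for dr in range(-radius_cells, radius_cells + 1)
        for dc in range(-radius_cells, radius_cells + 1)
        if dr * dr + dc * dc <= r2
    ]


def classify_terrain_position(
    dem: Grid,
    radius_cells: int = 5,
    scheme: TerrainScheme = DEFAULT_TERRAIN_SCHEME,
) -> EvidenceLayer:
    """Classify each cell by its elevation percentile within a circular window.

    The percentile is the mid-rank of the cell among all valid cells in the
    circular neighbourhood of ``radius_cells`` (the cell itself included):
    ``p = (#lower + 0.5·#equal) / #valid``. Ties are therefore broken by
    mid-rank, and a constant DEM sits at p = 0.5 (mid-slope) everywhere. At
    grid edges the neighbourhood is clipped to the raster. Cells whose
    neighbourhood holds no valid elevation become nodata.
    """
    if radius_cells < 1:
        raise ValueError("radius_cells must be >= 1")
    v = np.asarray(dem.values, dtype=float)
    valid = dem.valid_mask()
    if not valid.any():
        warnings.warn("DEM is entirely nodata; terrain layer is all nodata", stacklevel=2)
    pad = radius_cells
    vp = np.pad(np.where(valid, v, np.nan), pad, constant_values=np.nan)
    lower = np.zeros(v.shape)
    equal = np.zeros(v.shape)
    nvalid = np.zeros(v.shape)
    nr, nc = v.shape
    for dr, dc in _disk_offsets(radius_cells):
        nb = vp[pad + dr : pad + dr + nr, pad + dc : pad + dc + nc]
        ok = ~np.isnan(nb)
        lower += ok & (nb < v)
        equal += ok & (nb == v)
        nvalid += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (lower + 0.5 * equal) / nvalid
    codes = np.searchsorted(np.asarray(scheme.breaks), pct, side="right").astype(np.uint8)
    codes[~valid | (nvalid == 0)] = NODATA_CODE
    grid = Grid(codes, dem.cell_size, dem.origin, nodata=NODATA_CODE)
    return EvidenceLayer("terrain_position", grid, dict(enumerate(scheme.labels)))


def classify_elevation(dem: Grid, breaks_m: list[float] = (700.0, 1400.0)) -> EvidenceLayer:
    """Bin elevations into classes: class = number of breaks ≤ elevation.

    Bins are left-closed, right-open ([a, b)): a cell exactly at a break
    belongs to the class above it. k breaks yield k+1 classes; an empty break
    list degenerates (with a warning) to a single class.
    """
    breaks = np.asarray(breaks_m, dtype=float)
    if breaks.size and np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing")
    if breaks.size == 0:
        warnings.warn("no elevation breaks given: single-class elevation layer", stacklevel=2)
    valid = dem.valid_mask()
    codes = np.searchsorted(breaks, dem.values, side="right").astype(np.uint8)
    codes[~valid] = NODATA_CODE
    grid = Grid(codes, dem.cell_size, dem.origin, nodata=NODATA_CODE)
    labels = {i: f"elev_class_{i}" for i in range(len(breaks) + 1)}
    return EvidenceLayer("elevation", grid, labels)
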