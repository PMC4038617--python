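"""Raster, point and configuration I/O.

Rasters are stored as single-band TIFF (float32 for continuous layers,
uint8 for categorical) with the planar georeferencing — cell size, lower-left
origin, nodata — carried in a JSON document in the TIFF ImageDescription
tag. Points travel as CSV (columns ``x,y`` plus optional extras) or GeoJSON
Point features. Every CSV written by the pipeline starts with provenance
comment lines (stage, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import Grid, PointPattern

__all__ = [
    "RunConfig",
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "write_points_geojson",
    "read_points_geojson",
    "write_csv",
]

_META_KEY = "ricenest_georef"


def write_raster(grid: Grid, path) -> None:
    """Write a grid as single-band TIFF with a JSON georeferencing tag.

    Integer grids are stored as uint8 (bit-exact round trip); continuous
    grids as float32.
    """
    values = np.asarray(grid.values)
    if np.issubdtype(values.dtype, np.integer) or values.dtype == bool:
        data = values.astype(np.uint8)
    else:
        data = values.astype(np.float32)
    nodata = grid.nodata
    if nodata is not None and isinstance(nodata, float) and np.isnan(nodata):
        nodata = "nan"
    meta = {
        _META_KEY: {
            "cell_size": [grid.cell_size, grid.cell_size],
            "origin": list(grid.origin),
            "nodata": nodata,
        }
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_raster(path) -> Grid:
    """Read a TIFF written by :func:`write_raster`; square cells required."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        desc = page.description
    try:
        meta = json.loads(desc)[_META_KEY]
    except (json.JSONDecodeError, KeyError, TypeError):
        raise ValueError(f"{path}: missing planar transform metadata") from None
    sx, sy = meta["cell_size"]
    if sx != sy:
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
    nodata = meta.get("nodata")
    if nodata == "nan":
        nodata = float("nan")
    return Grid(data, float(sx), tuple(meta["origin"]), nodata)


def write_stack(probs: np.ndarray, cell_size: float, origin, path) -> None:
    """Write a (n_classes, nrows, ncols) probability stack as multi-band TIFF."""
    meta = {_META_KEY: {"cell_size": [cell_size, cell_size], "origin": list(origin), "nodata": "nan"}}
    tifffile.imwrite(path, np.asarray(probs, dtype=np.float32), description=json.dumps(meta))


def read_stack(path) -> tuple[np.ndarray, float, tuple[float, float]]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)[_META_KEY]
    except (json.JSONDecodeError, KeyError, TypeError):
        raise ValueError(f"{path}: missing planar transform metadata") from None
    sx, sy = meta["cell_size"]
    if sx != sy:
        raise ValueError(f"{path}: non-square cells are not supported")
    return np.asarray(data, dtype=float), float(sx), tuple(meta["origin"])


def _clip_to_window(pts: np.ndarray, window) -> np.ndarray:
    xmin, ymin, xmax, ymax = window
    inside = (pts[:, 0] > xmin) & (pts[:, 0] < xmax) & (pts[:, 1] > ymin) & (pts[:, 1] < ymax)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"rejected {n_out} point(s) outside the window", stacklevel=3)
    return pts[inside]


def read_points(path, window) -> PointPattern:
    """Read points from CSV (columns x, y) into a window from config/raster.

    Points outside the window are rejected with their count reported. An
    empty file yields an empty pattern with a warning.
    """
    df = pd.read_csv(path, comment="#")
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError(f"{path}: point CSV needs 'x' and 'y' columns")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if pts.shape[0] == 0:
        warnings.warn(f"{path}: no points", stacklevel=2)
    return PointPattern(_clip_to_window(pts, window), window, allow_duplicates=True)


def write_points(pattern: PointPattern, path, extra: dict[str, np.ndarray] | None = None,
                 header: list[str] | None = None) -> None:
    """Write points (plus optional per-point columns) as CSV."""
    data = {"x": pattern.points[:, 0], "y": pattern.points[:, 1]}
    if extra:
        data.update(extra)
    write_csv(pd.DataFrame(data), path, header)


def write_points_geojson(pattern: PointPattern, path, extra: dict[str, np.ndarray] | None = None) -> None:
    feats = []
    for i, (x, y) in enumerate(pattern.points):
        props = {k: _jsonable(v[i]) for k, v in (extra or {}).items()}
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": props,
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": feats,
        "bbox": list(pattern.window),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_points_geojson(path, window=None) -> PointPattern:
    with open(path) as fh:
        doc = json.load(fh)
    pts = np.array(
        [f["geometry"]["coordinates"] for f in doc.get("features", [])], dtype=float
    ).reshape(-1, 2)
    win = tuple(doc["bbox"]) if window is None and "bbox" in doc else window
    if win is None:
        raise ValueError(f"{path}: no window available (no bbox and none supplied)")
    return PointPattern(_clip_to_window(pts, win), win, allow_duplicates=True)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def write_csv(df: pd.DataFrame, path, header: list[str] | None = None) -> None:
    """Write a DataFrame with optional '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Parameters of a full synthetic run.

    Defaults describe the study conditions the pipeline emulates: a
    128x128-cell landscape at 100 m resolution (12.8 km window), relief
    370-2400 m, 768 stratified plots split in half, a habitat-anchored
    Thomas nest process (cluster spread 500 m), 3-km nest buffers, five nest
    clusters and three habitat-extent levels, and 95% Monte-Carlo envelopes.
    """

    nrows: int = 128
    ncols: int = 128
    cell_size: float = 100.0
    relief_range: tuple[float, float] = (370.0, 2400.0)
    smoothness: float = 4.0
    hypsometric_exponent: float = 2.0
    terrain_radius: int = 8
    elevation_breaks: tuple[float, ...] = (700.0, 1400.0)
    n_bands: int = 4
    noise_sd: float = 0.08
    n_plots: int = 768
    plot_size_m: float = 50.0
    n_parents: int = 8
    offspring_mean: float = 13.0
    sigma_m: float = 500.0
    association: float = 1.0
    focal_class: str = "winter_flooded_rice"
    uni_rmax: float = 6000.0
    uni_step: float = 500.0
    biv_rmax: float = 3000.0
    biv_step: float = 500.0
    nsim: int = 199
    alpha: float = 0.05
    buffer_radius: float = 3000.0
    k_nests: int = 5
    n_levels: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("relief_range", "elevation_breaks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["relief_range"] = list(d["relief_range"])
        d["elevation_breaks"] = list(d["elevation_breaks"])
        return d

    def digest(self) -> str:
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self, stage: str) -> list[str]:
        return [f"ricenest stage={stage} seed={self.seed} config={self.digest()}"]
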