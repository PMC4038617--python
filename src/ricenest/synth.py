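"""Synthetic landscape generation.

Builds every input the downstream pipeline consumes — a smooth DEM, a
seven-class land-cover map whose class occurrence depends on elevation and
terrain position, per-pixel multi-band spectra, a stratified field-plot
sample, and a clumped nest-site point pattern — so that classification
refinement, accuracy assessment and point-pattern analysis can all be
exercised without any field or satellite data.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import DEFAULT_SCHEME, ClassScheme, Grid, PlotSample, PointPattern

__all__ = [
    "SuitabilityRules",
    "default_suitability_rules",
    "default_class_spectra",
    "generate_dem",
    "generate_true_landcover",
    "generate_band_stack",
    "generate_sample_plots",
    "generate_nest_pattern",
]


def generate_dem(
    nrows: int,
    ncols: int,
    cell_size: float,
    relief_range: tuple[float, float] = (370.0, 2400.0),
    smoothness: float = 4.0,
    hypsometric_exponent: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> Grid:
    """Generate a smooth synthetic elevation model.

    A Gaussian random field: white noise smoothed with a Gaussian filter of
    standard deviation ``smoothness`` (in cells), normalised to [0, 1],
    raised to ``hypsometric_exponent`` and rescaled onto ``relief_range``.
    The exponent (> 1) skews the hypsometry towards low elevations,
    emulating a landscape of extensive plains rising into mountains; 1 gives
    the symmetric field. Being strictly monotone, the skew leaves
    rank-based terrain classification untouched. An infinite ``smoothness``
    yields the degenerate constant field at the midpoint of the relief range.
    """
    if nrows < 1 or ncols < 1:
        raise ValueError("grid dimensions must be positive")
    lo, hi = relief_range
    if not lo < hi:
        raise ValueError(f"relief_range must satisfy min < max, got {relief_range}")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if hypsometric_exponent <= 0:
        raise ValueError("hypsometric_exponent must be positive")
    mid = 0.5 * (lo + hi)
    if math.isinf(smoothness):
        return Grid(np.full((nrows, ncols), mid), cell_size)
    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=smoothness, mode="reflect")
    span = field.max() - field.min()
    if span < 1e-12:  # numerically flat: fall back to the degenerate limit
        values = np.full((nrows, ncols), mid)
    else:
        z = (field - field.min()) / span
        values = lo + (hi - lo) * z**hypsometric_exponent
    return Grid(values, cell_size)


@dataclass(frozen=True)
class SuitabilityRules:
    """Per-(elevation band, terrain class) class distributions.

    ``elevation_breaks_m`` bins the DEM into bands (left-closed, right-open);
    ``table`` maps (elevation_band, terrain_class) to a probability vector
    over the scheme's classes. Every distribution must sum to 1.
    """

    elevation_breaks_m: tuple[float, ...]
    table: dict[tuple[int, int], np.ndarray]

    def __post_init__(self) -> None:
        for key, p in self.table.items():
            p = np.asarray(p, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"rule distribution for {key} must be a probability vector summing to 1")
            object.__setattr__(self, "table", {**self.table, key: p})

    def distribution(self, elev_band: int, terrain_class: int) -> np.ndarray:
        try:
            return self.table[(elev_band, terrain_class)]
        except KeyError:
            raise KeyError(f"no suitability rule for elevation band {elev_band}, terrain class {terrain_class}") from None


def default_suitability_rules(scheme: ClassScheme = DEFAULT_SCHEME) -> SuitabilityRules:
    """Default class placement: rice and water in low gullies, forest high up.

    Elevation bands: below 700 m (valley/plain), 700–1400 m (mid-mountain;
    the focal bird is mostly seen below 1400 m), above 1400 m (high).
    Terrain classes 0..4 run gully → ridge. The distributions are decisive
    because real agricultural landscapes are strongly terrain-constrained —
    paddies occupy valley floors, rain-fed crops the slopes, forest the
    upper mountain — which is exactly the dependence the expert-system
    evidence exploits. Classes: winter_flooded_rice, winter_dry_rice,
    rain_fed, open_water, forest, shrub_grass, other.
    """
    low = np.array([
        [0.55, 0.12, 0.05, 0.15, 0.02, 0.03, 0.08],  # gully
        [0.30, 0.35, 0.12, 0.04, 0.05, 0.06, 0.08],  # lower mid-slope
        [0.08, 0.30, 0.35, 0.01, 0.08, 0.10, 0.08],  # mid-slope
        [0.02, 0.08, 0.35, 0.01, 0.25, 0.22, 0.07],  # upper mid-slope
        [0.01, 0.03, 0.20, 0.01, 0.35, 0.35, 0.05],  # ridge
    ])
    mid = np.array([
        [0.30, 0.10, 0.08, 0.07, 0.25, 0.15, 0.05],
        [0.12, 0.15, 0.12, 0.02, 0.35, 0.20, 0.04],
        [0.03, 0.06, 0.12, 0.01, 0.50, 0.25, 0.03],
        [0.01, 0.02, 0.05, 0.005, 0.62, 0.275, 0.02],
        [0.005, 0.01, 0.03, 0.005, 0.62, 0.31, 0.02],
    ])
    high = np.array([
        [0.01, 0.01, 0.02, 0.02, 0.70, 0.22, 0.02],
        [0.005, 0.005, 0.01, 0.01, 0.75, 0.21, 0.01],
        [0.002, 0.003, 0.005, 0.005, 0.77, 0.205, 0.01],
        [0.001, 0.002, 0.003, 0.004, 0.75, 0.23, 0.01],
        [0.001, 0.002, 0.003, 0.004, 0.70, 0.28, 0.01],
    ])
    w = {}
    for band, mat in enumerate((low, mid, high)):
        for terrain in range(5):
            row = mat[terrain]
            w[(band, terrain)] = row / row.sum()
    return SuitabilityRules(elevation_breaks_m=(700.0, 1400.0), table=w)


def generate_true_landcover(
    dem: Grid,
    terrain: Grid,
    scheme: ClassScheme = DEFAULT_SCHEME,
    suitability_rules: SuitabilityRules | None = None,
    seed: int | np.random.Generator = 0,
) -> Grid:
    """Draw a categorical land-cover map from terrain-conditioned distributions.

    Each cell's class is drawn independently from the rule distribution of
    its (elevation band, terrain position) stratum, so the true landscape
    genuinely depends on the evidence layers the expert system later uses.
    """
    if dem.shape != terrain.shape:
        raise ValueError("dem and terrain grids must share shape")
    rules = suitability_rules if suitability_rules is not None else default_suitability_rules(scheme)
    breaks = np.asarray(rules.elevation_breaks_m, dtype=float)
    elev_band = np.searchsorted(breaks, dem.values, side="right")
    rng = np.random.default_rng(seed)
    out = np.zeros(dem.shape, dtype=np.uint8)
    u = rng.random(dem.shape)
    for key in sorted({(int(b), int(t)) for b, t in zip(elev_band.ravel(), terrain.values.ravel())}):
        p = rules.distribution(*key)
        cdf = np.cumsum(p)
        mask = (elev_band == key[0]) & (terrain.values == key[1])
        out[mask] = np.searchsorted(cdf, u[mask], side="right").astype(np.uint8)
    out = np.minimum(out, scheme.n_classes - 1)  # guard against cdf rounding at u≈1
    scheme.validate_codes(out, nodata=None)
    return dem.like(out)


def default_class_spectra(scheme: ClassScheme = DEFAULT_SCHEME, n_bands: int = 4) -> dict[str, np.ndarray]:
    """Per-class mean reflectance vectors for the synthetic band stack.

    The two rice classes are spectrally close (winter scenes separate them
    poorly), as are forest and shrub/grass; terrain and elevation evidence is
    what disambiguates them downstream.
    """
    base = {
        "winter_flooded_rice": [0.15, 0.25, 0.10, 0.40],
        "winter_dry_rice": [0.18, 0.28, 0.12, 0.38],
        "rain_fed": [0.30, 0.35, 0.25, 0.30],
        "open_water": [0.08, 0.06, 0.03, 0.02],
        "forest": [0.05, 0.30, 0.45, 0.20],
        "shrub_grass": [0.08, 0.32, 0.42, 0.25],
        "other": [0.45, 0.42, 0.40, 0.35],
    }
    out = {}
    for name in scheme.names:
        vec = np.asarray(base.get(name, np.linspace(0.1, 0.5, 4)), dtype=float)
        if n_bands != 4:  # tile/trim to the requested band count
            vec = np.resize(vec, n_bands)
        out[name] = vec
    return out


def generate_band_stack(
    truth: Grid,
    class_spectra: dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.08,
    scheme: ClassScheme = DEFAULT_SCHEME,
    n_bands: int = 4,
    seed: int | np.random.Generator = 0,
) -> list[Grid]:
    """Per-pixel spectra: class mean vector plus independent Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    spectra = class_spectra if class_spectra is not None else default_class_spectra(scheme, n_bands)
    missing = [n for n in scheme.names if n not in spectra]
    if missing:
        raise ValueError(f"missing class spectra for {missing}")
    means = np.stack([np.asarray(spectra[n], dtype=float) for n in scheme.names])
    if means.shape[1] != n_bands:
        n_bands = means.shape[1]
    rng = np.random.default_rng(seed)
    codes = truth.values.astype(int)
    bands = []
    for b in range(n_bands):
        clean = means[codes, b]
        noisy = clean + (rng.normal(0.0, noise_sd, truth.shape) if noise_sd > 0 else 0.0)
        bands.append(truth.like(np.asarray(noisy, dtype=float)))
    return bands


def generate_sample_plots(
    truth: Grid,
    n_plots: int = 768,
    plot_size_m: float = 50.0,
    scheme: ClassScheme = DEFAULT_SCHEME,
    seed: int | np.random.Generator = 0,
) -> PlotSample:
    """Stratified random field plots, split 50/50 into train and test halves.

    Plots are allocated to strata proportionally to stratum area (largest
    remainder), with at least two plots per stratum present on the map so
    every class reaches both halves. The plot label is the truth class at the
    plot-centre cell; the split is stratified, so each half receives half of
    every stratum (odd leftovers are balanced across strata to keep the
    halves exactly equal).
    """
    if n_plots % 2 != 0:
        raise ValueError("n_plots must be even: the sample splits into equal halves")
    if plot_size_m <= 0:
        raise ValueError("plot_size_m must be positive")
    rng = np.random.default_rng(seed)
    codes = truth.values.astype(int)
    present = np.unique(codes)
    counts = {int(c): int((codes == c).sum()) for c in present}
    total = sum(counts.values())
    # largest-remainder proportional allocation, floor 2 per present stratum
    quota = {c: n_plots * counts[c] / total for c in counts}
    alloc = {c: int(math.floor(q)) for c, q in quota.items()}
    rem = n_plots - sum(alloc.values())
    for c in sorted(counts, key=lambda c: quota[c] - alloc[c], reverse=True)[:rem]:
        alloc[c] += 1
    # floor so every present stratum reaches both halves (4 when budget allows)
    floor = 4 if n_plots >= 4 * len(counts) else 2
    for c in counts:
        while alloc[c] < min(floor, counts[c]):
            donor = max(alloc, key=lambda d: alloc[d])
            alloc[donor] -= 1
            alloc[c] += 1

    xs, ys, labels, split = [], [], [], []
    leftovers: list[int] = []  # indices of per-stratum odd plots, balanced later
    for c in sorted(alloc):
        k = min(alloc[c], counts[c])
        flat = np.flatnonzero(codes == c)
        chosen = rng.choice(flat, size=k, replace=False)
        for idx in chosen:
            r, col = divmod(int(idx), truth.ncols)
            cx, cy = truth.cell_center(r, col)
            xs.append(cx)
            ys.append(cy)
            labels.append(int(codes[r, col]))
        order = rng.permutation(k)
        half = k // 2
        marks = np.empty(k, dtype=object)
        marks[order[:half]] = "train"
        marks[order[half : 2 * half]] = "test"
        if k % 2:
            leftovers.append(len(split) + int(order[-1]))
            marks[order[-1]] = None
        split.extend(marks)
    rng.shuffle(leftovers)
    for i, idx in enumerate(leftovers):
        split[idx] = "train" if i % 2 == 0 else "test"
    return PlotSample(
        np.array(xs), np.array(ys), np.array(labels, dtype=int), np.array(split, dtype=object)
    )


def patchy_habitat(
    nrows: int = 128,
    ncols: int = 128,
    cell_size: float = 100.0,
    n_patches: int = 4,
    patch_halfwidth: int = 6,
    margin: int = 8,
    seed: int | np.random.Generator = 0,
) -> Grid:
    """A sparse habitat mask of compact square patches.

    Emulates a landscape where the focal habitat occurs as a few isolated
    patches (a strong, well-defined alternative for association power
    studies), in contrast to the extensive lowland habitat of the full
    landscape generator. Returns a binary grid (1 = habitat).
    """
    rng = np.random.default_rng(seed)
    v = np.zeros((nrows, ncols), dtype=np.uint8)
    lo = patch_halfwidth + margin
    for _ in range(n_patches):
        r = int(rng.integers(lo, nrows - lo))
        c = int(rng.integers(lo, ncols - lo))
        v[r - patch_halfwidth : r + patch_halfwidth, c - patch_halfwidth : c + patch_halfwidth] = 1
    return Grid(v, cell_size)


def generate_nest_pattern(
    habitat_mask: Grid,
    n_parents: int = 8,
    offspring_mean: float = 13.0,
    sigma_m: float = 500.0,
    association: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> PointPattern:
    """Clumped nest sites from a habitat-anchored Thomas cluster process.

    Parent (cluster-centre) placement: with probability ``association`` a
    parent is dropped uniformly inside a uniformly chosen habitat cell,
    otherwise uniformly in the window. Each parent receives a
    Poisson(``offspring_mean``) number of nests displaced by an isotropic
    Gaussian of standard deviation ``sigma_m``; nests falling outside the
    window are redrawn (not clipped), keeping intensity homogeneous near the
    edges. ``association=0`` yields a habitat-independent clustered pattern;
    ``association=1`` anchors every cluster on habitat.
    """
    if not 0.0 <= association <= 1.0:
        raise ValueError("association must lie in [0, 1]")
    if sigma_m <= 0:
        raise ValueError("sigma_m must be positive")
    if n_parents < 1:
        raise ValueError("need at least one parent")
    mask = habitat_mask.values.astype(bool)
    if association > 0 and not mask.any():
        raise ValueError("habitat mask is empty but association > 0")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = habitat_mask.window()
    cell = habitat_mask.cell_size
    habitat_cells = np.flatnonzero(mask)

    parents = np.empty((n_parents, 2))
    on_habitat = rng.random(n_parents) < association
    for i in range(n_parents):
        if on_habitat[i]:
            idx = int(rng.choice(habitat_cells))
            r, c = divmod(idx, habitat_mask.ncols)
            cx, cy = habitat_mask.cell_center(r, c)
            parents[i] = (cx + (rng.random() - 0.5) * cell, cy + (rng.random() - 0.5) * cell)
        else:
            parents[i] = (xmin + rng.random() * (xmax - xmin), ymin + rng.random() * (ymax - ymin))

    pts = []
    for i in range(n_parents):
        for _ in range(int(rng.poisson(offspring_mean))):
            while True:
                p = parents[i] + rng.normal(0.0, sigma_m, 2)
                if xmin < p[0] < xmax and ymin < p[1] < ymax:
                    pts.append(p)
                    break
    points = np.array(pts) if pts else np.empty((0, 2))
    return PointPattern(points, (xmin, ymin, xmax, ymax))
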