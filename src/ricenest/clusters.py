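"""Habitat quantification around nests, Ward clustering, and group tests.

The focal habitat class is converted to cell-centre points, the habitat area
inside a fixed-radius buffer is tallied per nest, nests are grouped by
Ward's hierarchical method (geographical clusters; habitat-extent levels),
and differences among groups are tested with Kruskal-Wallis / pairwise
Mann-Whitney (areas) and one-way ANOVA / Tukey HSD (bivariate L values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .grids import Grid, PointPattern

__all__ = [
    "BufferAreaTable",
    "ClusterResult",
    "raster_class_to_points",
    "buffer_class_area",
    "ward_cluster",
    "group_tests",
    "envelope_anova",
]


def raster_class_to_points(class_map: Grid, focal_class: int) -> PointPattern:
    """One point at the centre of every cell of the focal class.

    The observation window is the raster extent. An empty result (no focal
    cells) is returned with a warning rather than as an error.
    """
    mask = class_map.values == focal_class
    if not mask.any():
        warnings.warn(f"no cells of class {focal_class}: empty point pattern", stacklevel=2)
        return PointPattern(np.empty((0, 2)), class_map.window())
    cx, cy = class_map.cell_centers()
    pts = np.column_stack([cx[mask], cy[mask]])
    return PointPattern(pts, class_map.window())


@dataclass
class BufferAreaTable:
    """Per-nest focal-habitat area (hectares) within a buffer radius.

    Areas are bounded by the buffer disc dilated by half a cell diagonal —
    the exact upper bound for cell-centre counting, where a boundary cell
    whose centre is just inside the radius contributes its full area.
    """

    x: np.ndarray
    y: np.ndarray
    area_ha: np.ndarray
    radius_m: float
    cell_size: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.area_ha < 0):
            raise ValueError("areas must be non-negative")
        reach = self.radius_m + self.cell_size * np.sqrt(0.5)
        if np.any(self.area_ha > np.pi * reach**2 / 1e4 + 1e-9):
            raise ValueError("buffer area exceeds the geometric buffer size")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "area_ha": self.area_ha})


def buffer_class_area(
    class_map: Grid,
    nests: PointPattern,
    radius_m: float = 3000.0,
    focal_class: int = 0,
) -> BufferAreaTable:
    """Habitat area within ``radius_m`` of each nest, by cell-centre counting.

    A cell contributes its full area when its centre lies within the
    Euclidean buffer distance of the nest (raster zonal-statistics
    semantics); partial-cell geometry is ignored. Buffers extending past the
    raster edge simply find no cells there.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    mask = class_map.values == focal_class
    cell_ha = class_map.cell_size**2 / 1e4
    if not mask.any():
        areas = np.zeros(nests.n)
    else:
        cx, cy = class_map.cell_centers()
        tree = cKDTree(np.column_stack([cx[mask], cy[mask]]))
        counts = tree.query_ball_point(nests.points, r=radius_m, return_length=True)
        areas = np.asarray(counts, dtype=float) * cell_ha
    return BufferAreaTable(
        nests.points[:, 0].copy(), nests.points[:, 1].copy(), areas, radius_m, class_map.cell_size
    )


@dataclass
class ClusterResult:
    """Ward clustering outcome: labels in 1..k plus the merge history.

    ``merges`` records, step by step, the two cluster ids merged and the
    increase in within-cluster error sum of squares (the Ward merge cost);
    for squared-Euclidean ESS the cost sequence is non-decreasing (no
    reversals). Cluster ids follow the scipy convention: originals 0..n-1,
    each merge creates id n+step. Final labels are renumbered 1..k by
    ascending cluster centroid (first coordinate) for reproducibility.
    """

    labels: np.ndarray
    k: int
    merges: list[tuple[int, int, float]]
    centroids: np.ndarray

    def __post_init__(self) -> None:
        found = np.unique(self.labels)
        if len(found) != self.k or found.min() != 1 or found.max() != self.k:
            raise ValueError("labels must cover 1..k with every cluster non-empty")


def ward_cluster(features: np.ndarray, k: int) -> ClusterResult:
    """Agglomerative Ward clustering cut at k clusters.

    At each step the pair of clusters whose merge least increases the total
    within-cluster error sum of squares is joined; the increase is
    Δ(A, B) = |A||B| / (|A| + |B|) · ‖c_A − c_B‖², maintained through the
    Lance-Williams recurrence. Cost ties break to the lexicographically
    smallest cluster-id pair.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError(f"cannot form k={k} clusters from {n} items")

    size = {i: 1 for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    # initial merge costs between singletons: ||xi - xj||^2 / 2
    cost: dict[tuple[int, int], float] = {}
    for i in range(n):
        diff = X[i + 1 :] - X[i]
        d2 = np.einsum("ij,ij->i", diff, diff)
        for off, j in enumerate(range(i + 1, n)):
            cost[(i, j)] = 0.5 * d2[off]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(size) > k:
        (a, b), c_ab = min(cost.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, c_ab))
        new = next_id
        next_id += 1
        sa, sb = size[a], size[b]
        for other in list(size):
            if other in (a, b):
                continue
            key_a = (min(a, other), max(a, other))
            key_b = (min(b, other), max(b, other))
            so = size[other]
            # Lance-Williams for Ward's ESS-increase cost
            c_new = (
                (sa + so) * cost.pop(key_a) + (sb + so) * cost.pop(key_b) - so * c_ab
            ) / (sa + sb + so)
            cost[(min(new, other), max(new, other))] = c_new
        cost.pop((a, b))
        members[new] = members.pop(a) + members.pop(b)
        size[new] = sa + sb
        del size[a], size[b]

    groups = list(members)
    cents = np.array([X[members[g]].mean(axis=0) for g in groups])
    order = np.argsort(cents[:, 0], kind="stable")
    labels = np.empty(n, dtype=int)
    for rank, gi in enumerate(order, start=1):
        labels[members[groups[gi]]] = rank
    return ClusterResult(labels, k, merges, cents[order])


@dataclass
class GroupTestResult:
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group_a, group_b, U, p, significant, p_holm


def group_tests(groups: dict[int, np.ndarray] | list[np.ndarray], alpha: float = 0.05) -> GroupTestResult:
    """Kruskal-Wallis over all groups plus all pairwise Mann-Whitney U tests.

    Pairwise p-values are reported raw, with pairs at p ≥ alpha flagged as
    not significant; a Holm-adjusted column is emitted alongside.
    """
    if not isinstance(groups, dict):
        groups = {i + 1: g for i, g in enumerate(groups)}
    keys = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in keys]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    h, p = stats.kruskal(*arrays)
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            u, pu = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            rows.append(
                {"group_a": keys[i], "group_b": keys[j], "U": float(u), "p": float(pu)}
            )
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < alpha
    table["p_holm"] = multipletests(table["p"], method="holm")[1]
    return GroupTestResult(float(h), float(p), table)


@dataclass
class AnovaResult:
    f: float | None  # None when F is undefined (no within-group variance anywhere)
    p: float | None
    tukey: pd.DataFrame  # group_a, group_b, diff, p_adj, significant


def envelope_anova(groups: dict[int, np.ndarray] | list[np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA over per-cluster L12 samples, with Tukey HSD post-hoc.

    Each group pools the observed bivariate L values of one nest cluster over
    the bivariate radius grid. With zero within-group variance in every group
    the F statistic is undefined and reported as such.
    """
    if not isinstance(groups, dict):
        groups = {i + 1: g for i, g in enumerate(groups)}
    keys = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in keys]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least two groups of at least two values each")
    if all(np.ptp(a) == 0 for a in arrays):
        empty = pd.DataFrame(columns=["group_a", "group_b", "diff", "p_adj", "significant"])
        return AnovaResult(None, None, empty)
    f, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(groups[g]) for g in keys])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    tukey = pd.DataFrame(
        {
            "group_a": frame["group1"],
            "group_b": frame["group2"],
            "diff": frame["meandiff"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
            "significant": frame["reject"].astype(bool),
        }
    )
    return AnovaResult(float(f), float(p), tukey)
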