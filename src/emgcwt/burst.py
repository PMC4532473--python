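"""Burst segmentation and morphology on cycle-averaged power maps.

The averaged percent-cycle map shows one dominant high-power region per activation
burst.  Its pixels are partitioned into four power classes by multi-level Otsu
thresholding of the linear power histogram; the top class isolates the burst (and
suppresses low-power artifacts).  Connected components of the top-class mask are the
candidate bursts; the one with maximum area (or maximum mean power — the two agree on
well-formed maps) is quantified by

* main frequency: the power-weighted centroid of the region, in Hz,
* mean power: arithmetic mean of map power over the region's pixels,
* area: the region's pixel count on the 496 x 401 grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cyclemap import CycleMap

__all__ = [
    "OtsuResult",
    "BurstRegion",
    "BurstMetrics",
    "otsu_multiclass",
    "highest_class_mask",
    "connected_regions",
    "select_burst",
    "weighted_centroid",
    "burst_metrics",
    "analyze_cycle_map",
]


@dataclass
class OtsuResult:
    """Multi-level Otsu thresholds over the linear power histogram.

    ``n_classes - 1`` strictly ascending thresholds partition values into
    ``n_classes`` classes; thresholds are histogram bin edges on ``[0, max]``.
    """

    thresholds: np.ndarray
    n_classes: int
    bin_edges: np.ndarray

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Class label per value: 0 (lowest power) .. n_classes - 1 (highest)."""
        return np.digitize(np.asarray(values, dtype=float), self.thresholds)


def _class_moments(counts: np.ndarray, centers: np.ndarray):
    """Cumulative weight/mean sums so any bin interval's Otsu score is O(1)."""
    w = counts / counts.sum()
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cm = np.concatenate(([0.0], np.cumsum(w * centers)))
    return cw, cm


def _interval_scores(cw: np.ndarray, cm: np.ndarray) -> np.ndarray:
    """score[i, j] = W * mu^2 of the bin interval [i, j) (0 where W == 0)."""
    W = cw[None, :] - cw[:, None]
    M = cm[None, :] - cm[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(W > 0, M * M / np.where(W > 0, W, 1.0), 0.0)
    return score


def otsu_multiclass(values, n_classes: int = 4, bins: int = 256) -> OtsuResult:
    """Exact multi-level Otsu thresholding.

    Builds a ``bins``-bin histogram of the values over ``[0, max]`` and finds the
    threshold set that maximizes the between-class variance (equivalently minimizes
    the weighted within-class variance) by dynamic programming over bin boundaries —
    a global optimum, identical to exhaustive search.  Ties are broken toward the
    lowest thresholds.

    Raises
    ------
    ValueError
        For degenerate input (fewer than ``n_classes`` distinct values, or a
        non-positive maximum).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    vmax = v.max()
    if not vmax > 0:
        raise ValueError("degenerate input: maximum value must be positive")
    if np.unique(v).size < n_classes:
        raise ValueError("degenerate input: fewer distinct values than classes")

    edges = np.linspace(0.0, vmax, bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    cw, cm = _class_moments(counts, centers)
    score = _interval_scores(cw, cm)

    # dp[c, j]: best total score splitting bins [0, j) into c+1 classes;
    # each class spans >= 1 bin.  np.argmax keeps the earliest (lowest) boundary.
    n_thr = n_classes - 1
    dp = score[0].copy()  # one class over [0, j)
    choice = np.zeros((n_thr, bins + 1), dtype=int)
    for c in range(1, n_classes):
        cand = dp[:, None] + score  # cand[i, j]: boundary at i
        cand[np.tril_indices(bins + 1, k=0)] = -np.inf  # require boundary i < j
        cand[:c, :] = -np.inf  # earlier classes need >= c bins
        choice[c - 1] = np.argmax(cand, axis=0)
        dp = cand[choice[c - 1], np.arange(bins + 1)]

    boundaries = np.empty(n_thr, dtype=int)
    j = bins
    for c in range(n_classes - 1, 0, -1):
        j = int(choice[c - 1, j])
        boundaries[c - 1] = j
    thresholds = edges[boundaries]
    if not np.all(np.diff(thresholds) > 0):
        raise ValueError("degenerate histogram: thresholds not strictly ascending")
    return OtsuResult(thresholds=thresholds, n_classes=n_classes, bin_edges=edges)


def highest_class_mask(
    cycle_map, otsu: OtsuResult, fallback_to_next_class: bool = False
) -> np.ndarray:
    """Mask of the highest-power Otsu class (power strictly above the top threshold).

    If no pixel exceeds the top threshold, raises unless ``fallback_to_next_class``
    allows merging the top two classes.
    """
    power = cycle_map.power if hasattr(cycle_map, "power") else np.asarray(cycle_map)
    mask = power > otsu.thresholds[-1]
    if not mask.any():
        if fallback_to_next_class and otsu.thresholds.size >= 2:
            mask = power > otsu.thresholds[-2]
        if not mask.any():
            raise ValueError("no pixel above the top Otsu threshold")
    return mask


@dataclass
class BurstRegion:
    """One 4-connected component of the top-class mask."""

    rows: np.ndarray
    cols: np.ndarray
    area: int
    mean_power: float
    centroid_row: float  # power-weighted, in pixel coordinates
    centroid_col: float


def connected_regions(
    mask: np.ndarray, power: np.ndarray, connectivity: int = 1
) -> list[BurstRegion]:
    """Maximal connected components of a mask (4-connected by default).

    ``connectivity=1`` means edge-adjacency only (diagonal neighbours are separate
    regions); ``connectivity=2`` adds diagonals.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    regions = []
    for lbl in range(1, n + 1):
        rows, cols = np.nonzero(labels == lbl)
        p = power[rows, cols]
        total = p.sum()
        if total > 0:
            cr = float((p * rows).sum() / total)
            cc = float((p * cols).sum() / total)
        else:  # uniform zero-power region: geometric centroid
            cr, cc = float(rows.mean()), float(cols.mean())
        regions.append(
            BurstRegion(
                rows=rows,
                cols=cols,
                area=int(rows.size),
                mean_power=float(p.mean()),
                centroid_row=cr,
                centroid_col=cc,
            )
        )
    return regions


def select_burst(regions: list[BurstRegion], criterion: str = "max_area") -> BurstRegion:
    """Pick the analysis burst among candidate regions.

    ``"max_area"`` or ``"max_mean_power"``; ties fall back to the other criterion,
    then to the lowest centroid frequency row, making the choice deterministic.
    """
    if len(regions) == 0:
        raise ValueError("no candidate regions")
    if criterion == "max_area":
        key = lambda r: (r.area, r.mean_power, -r.centroid_row)
    elif criterion == "max_mean_power":
        key = lambda r: (r.mean_power, r.area, -r.centroid_row)
    else:
        raise ValueError("criterion must be 'max_area' or 'max_mean_power'")
    return max(regions, key=key)


def weighted_centroid(region: BurstRegion, cycle_map: CycleMap) -> tuple[float, float]:
    """Power-weighted centroid of a region in physical units (Hz, % of cycle)."""
    p = cycle_map.power[region.rows, region.cols]
    total = p.sum()
    if not total > 0:
        raise ValueError("region has zero total power")
    row = float((p * region.rows).sum() / total)
    col = float((p * region.cols).sum() / total)
    freq = float(np.interp(row, np.arange(cycle_map.frequencies.size), cycle_map.frequencies))
    pct = float(np.interp(col, np.arange(cycle_map.percent.size), cycle_map.percent))
    return freq, pct


@dataclass
class BurstMetrics:
    """The burst-morphology dependent variables."""

    main_frequency_hz: float
    centroid_percent: float
    mean_power: float
    area_px: int


def burst_metrics(region: BurstRegion, cycle_map: CycleMap) -> BurstMetrics:
    """Main (weighted-centroid) frequency, mean power, and pixel area of a burst."""
    freq, pct = weighted_centroid(region, cycle_map)
    mean_p = float(cycle_map.power[region.rows, region.cols].mean())
    return BurstMetrics(
        main_frequency_hz=freq,
        centroid_percent=pct,
        mean_power=mean_p,
        area_px=region.area,
    )


def analyze_cycle_map(
    cycle_map: CycleMap,
    bins: int = 256,
    connectivity: int = 1,
    criterion: str = "max_area",
    fallback_to_next_class: bool = False,
) -> BurstMetrics:
    """Full burst quantification of one cycle-averaged map.

    Otsu 4-class segmentation -> top-class mask -> connected components -> burst
    selection -> metrics.
    """
    otsu = otsu_multiclass(cycle_map.power, n_classes=4, bins=bins)
    mask = highest_class_mask(cycle_map, otsu, fallback_to_next_class)
    regions = connected_regions(mask, cycle_map.power, connectivity=connectivity)
    burst = select_burst(regions, criterion=criterion)
    return burst_metrics(burst, cycle_map)
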