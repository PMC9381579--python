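"""Junction image -> per-cell shape metrics.

Pipeline for monolayers stained for a tight-junction marker (ZO-1):

1. ``preprocess``       — maximum filter, Gaussian blur, threshold -> junction mask
2. ``partition_cells``  — label cell interiors, assign junction pixels to the
                          nearest interior (geometric Voronoi influence zones)
3. ``postfilter_labels``— fill holes, dilate labels, drop border-touching and
                          undersized labels
4. ``measure_shapes``   — area, Crofton perimeter, convex perimeter,
                          convexity, geodesic diameter per cell
5. ``summarize_distribution`` / ``compare_groups`` — per-group histograms and
                          a rank-based omnibus test

Area is the raw pixel count; convexity is convex perimeter / perimeter
(1 for convex cells, smaller for irregular ones); geodesic diameter is the
longest within-cell shortest path (see :mod:`rpekit.geodesic`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.stats import kruskal, iqr
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, find_boundaries

from .geodesic import geodesic_diameter

logger = logging.getLogger(__name__)

ALL_METRICS = ("area", "perimeter", "convexity", "geodesic_diameter")


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable parameters of the segmentation/measurement pipeline.

    The defaults are conservative: a small maximum filter closes gaps in the
    junction staining, sigma-2 blur suppresses speckle before Otsu
    thresholding, interiors are 4-connected so that diagonally touching
    cells stay separate, and cells under 50 px are treated as debris.
    """

    max_filter_radius_px: int = 2
    gaussian_sigma_px: float = 2.0
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.5
    connectivity: int = 4  # interior labelling connectivity (4 or 8)
    label_dilation_px: int = 1
    min_cell_area_px: int = 50
    geodesic_metric: str = "chamfer_1_sqrt2"
    convex_perimeter_method: str = "hull_polygon"  # or "crofton_hull"

    def __post_init__(self) -> None:
        if self.max_filter_radius_px < 0:
            raise ValueError("max_filter_radius_px must be >= 0")
        if self.gaussian_sigma_px < 0:
            raise ValueError("gaussian_sigma_px must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.label_dilation_px < 0 or self.min_cell_area_px < 0:
            raise ValueError("dilation and min area must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellLabelMap:
    """Integer-labelled partition of the image (0 = unassigned/background)."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def preprocess(image: np.ndarray, config: MorphometryConfig = MorphometryConfig()) -> np.ndarray:
    """Binary junction mask from a grayscale junction-stained image."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValueError("expected a 2D grayscale image of at least 64x64 px")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if config.max_filter_radius_px > 0:
        size = 2 * config.max_filter_radius_px + 1
        img = ndi.maximum_filter(img, size=size)
    if config.gaussian_sigma_px > 0:
        img = ndi.gaussian_filter(img, config.gaussian_sigma_px)
    if np.ptp(img) == 0:
        raise ValueError("no junction signal: image is constant after filtering")
    if config.threshold_method == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = config.fixed_threshold
    return img > thr


def partition_cells(mask: np.ndarray, config: MorphometryConfig = MorphometryConfig()) -> CellLabelMap:
    """Partition the image into cells from a binary junction mask.

    The inverted mask's connected components are the cell interiors; every
    junction pixel is then handed to its geometrically nearest interior
    (influence zones of the Euclidean distance transform), so label
    ownership is a total function on all pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("mask is all foreground: no cell interiors")
    structure = (
        ndi.generate_binary_structure(2, 1)
        if config.connectivity == 4
        else ndi.generate_binary_structure(2, 2)
    )
    interiors, n = ndi.label(~mask, structure=structure)
    if n == 0:
        raise ValueError("no interior components found")
    # influence zones: nearest labelled pixel for every junction pixel
    _, (ir, ic) = ndi.distance_transform_edt(interiors == 0, return_indices=True)
    labels = interiors[ir, ic]
    return CellLabelMap(labels=labels.astype(np.int32), provenance={"config": config.to_dict(), "n_interiors": int(n)})


def postfilter_labels(labelmap: CellLabelMap, config: MorphometryConfig = MorphometryConfig()) -> CellLabelMap:
    """Second-round label filtering: fill holes, dilate, drop edge/small labels."""
    labels = labelmap.labels.copy()
    # fill holes label-wise: a hole is a background pocket fully inside one label
    if (labels == 0).any():
        filled = ndi.binary_fill_holes(labels > 0)
        holes, nh = ndi.label(filled & (labels == 0))
        for h in range(1, nh + 1):
            hole = holes == h
            ring = ndi.binary_dilation(hole) & ~hole
            owners = np.unique(labels[ring])
            owners = owners[owners > 0]
            if len(owners) == 1:
                labels[hole] = owners[0]
    if config.label_dilation_px > 0:
        labels = expand_labels(labels, distance=config.label_dilation_px)
    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    for lb in np.unique(labels[border]):
        if lb > 0:
            labels[labels == lb] = 0
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    for lb, c in zip(ids, counts):
        if c < config.min_cell_area_px:
            labels[labels == lb] = 0
    # renumber contiguously, preserving scan order
    remaining = np.unique(labels[labels > 0])
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[remaining] = np.arange(1, len(remaining) + 1)
    labels = lut[labels]
    if labels.max() == 0:
        logger.warning("postfilter_labels removed every label")
    prov = dict(labelmap.provenance)
    prov["postfiltered"] = True
    return CellLabelMap(labels=labels, provenance=prov)


def _convex_perimeter(prop, method: str) -> float:
    if method == "crofton_hull":
        from skimage.measure import perimeter_crofton

        return float(perimeter_crofton(prop.image_convex, directions=4))
    boundary = find_boundaries(np.pad(prop.image, 1), mode="inner")
    pts = np.argwhere(boundary)
    if len(pts) < 3:
        return float("nan")
    try:
        hull = ConvexHull(pts.astype(float))
    except Exception:  # collinear boundary (1-px lines)
        span = pts.max(0) - pts.min(0)
        return 2.0 * float(np.hypot(*span))
    verts = pts[hull.vertices].astype(float)
    diffs = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def measure_shapes(
    labelmap: CellLabelMap,
    pixel_size_um: float | None = None,
    config: MorphometryConfig = MorphometryConfig(),
    metrics: tuple[str, ...] = ALL_METRICS,
) -> pd.DataFrame:
    """Per-cell shape metrics; one row per label.

    Columns: cell_id, area_px (pixel count), perimeter_px (Crofton,
    4 directions), convex_perimeter_px, convexity, geodesic_diameter_px,
    touches_edge, excluded, and area_um2 when a pixel size is given.
    Degenerate labels (too few boundary pixels for a hull) are flagged
    ``excluded`` rather than dropped.
    """
    labels = labelmap.labels
    if labels.max() == 0:
        raise ValueError("no labels to measure")
    rows = []
    H, W = labels.shape
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        rec: dict = {"cell_id": int(prop.label), "area_px": int(prop.area)}
        rec["touches_edge"] = bool(r0 == 0 or c0 == 0 or r1 == H or c1 == W)
        excluded = False
        if "perimeter" in metrics or "convexity" in metrics:
            rec["perimeter_px"] = float(prop.perimeter_crofton)
        if "convexity" in metrics:
            cp = _convex_perimeter(prop, config.convex_perimeter_method)
            rec["convex_perimeter_px"] = cp
            if not np.isfinite(cp) or rec["perimeter_px"] <= 0:
                excluded = True
                rec["convexity"] = float("nan")
            else:
                rec["convexity"] = cp / rec["perimeter_px"]
        if "geodesic_diameter" in metrics:
            rec["geodesic_diameter_px"] = geodesic_diameter(
                prop.image, metric=config.geodesic_metric
            )
        if prop.area == 1:
            excluded = True
        rec["excluded"] = excluded
        if pixel_size_um is not None:
            rec["area_um2"] = prop.area * pixel_size_um**2
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_distribution(
    records: pd.DataFrame,
    metric: str,
    bins: int | np.ndarray = 20,
    group: str = "",
) -> dict:
    """Histogram + median/IQR/CV summary of one metric over non-excluded cells."""
    col = {"area": "area_px", "convexity": "convexity", "geodesic_diameter": "geodesic_diameter_px", "perimeter": "perimeter_px"}.get(metric, metric)
    kept = records.loc[~records["excluded"], col].dropna().to_numpy()
    n_dropped = len(records) - len(kept)
    if len(kept) == 0:
        raise ValueError("all records excluded; nothing to summarise")
    if n_dropped:
        logger.info("summarize_distribution: dropped %d excluded records", n_dropped)
    counts, edges = np.histogram(kept, bins=bins)
    freq = counts / counts.sum()
    mean = float(np.mean(kept))
    return {
        "group": group,
        "metric": metric,
        "bin_edges": edges,
        "counts": counts,
        "frequencies": freq,
        "n": int(len(kept)),
        "median": float(np.median(kept)),
        "iqr": float(iqr(kept)),
        "cv": float(np.std(kept) / mean) if mean != 0 else float("nan"),
        "values": kept,
    }


def compare_groups(distributions: list[dict], alpha: float = 0.05) -> dict:
    """Rank-based omnibus comparison (Kruskal-Wallis) of per-cell metric values."""
    if len(distributions) < 2:
        raise ValueError("need at least two groups to compare")
    for d in distributions:
        if d["n"] < 3:
            raise ValueError(f"group {d['group']!r} has fewer than 3 cells")
    samples = [d["values"] for d in distributions]
    stat, p = kruskal(*samples)
    grand_n = sum(len(s) for s in samples)
    # epsilon-squared effect size for the H statistic
    eps2 = (stat - len(samples) + 1) / (grand_n - len(samples))
    return {
        "test": "kruskal-wallis",
        "statistic": float(stat),
        "pvalue": float(p),
        "significant": bool(p < alpha),
        "alpha": alpha,
        "groups": {d["group"]: {"n": d["n"], "median": d["median"], "iqr": d["iqr"]} for d in distributions},
        "effect_epsilon_sq": float(eps2),
    }
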