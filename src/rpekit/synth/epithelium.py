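"""Synthetic junction-stained epithelium images with exact geometric truth.

Emulates a confluent epithelial monolayer imaged by tight-junction
immunostaining (e.g. ZO-1): bright junction lines on dark cell interiors.
Cells are the Voronoi tessellation of seed points; regularity is controlled
by Lloyd (centroidal) relaxation and irregularity by Gaussian jitter of the
relaxed seeds, so the two knobs are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, GeometryCollection, MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree


class SeedCollisionError(RuntimeError):
    """Raised when jittered seeds remain closer than twice the junction width."""


@dataclass(frozen=True)
class EpitheliumSpec:
    """Parameters of one synthetic monolayer image.

    Attributes
    ----------
    width_px, height_px : int
        Image size in pixels.
    n_cells : int
        Number of Voronoi seed points (cells before edge clipping).
    lloyd_iterations : int
        Centroidal relaxation steps; more steps give a more regular,
        honeycomb-like tessellation.
    jitter_sigma_px : float
        SD of Gaussian displacement applied to the relaxed seeds;
        larger values give more irregular cell shapes.
    junction_width_px : float
        Width of the bright junction band drawn along cell boundaries.
    background_margin_px : int
        Dark frame around the tessellated foreground (0 = cells fill image).
    noise_sd : float
        Additive Gaussian noise SD on the [0, 1] intensity scale.
    blur_sigma_px : float
        Gaussian blur applied before noise (optical point-spread stand-in).
    rng_seed : int
        Seed; identical specs produce bit-identical images.
    """

    width_px: int = 512
    height_px: int = 512
    n_cells: int = 150
    lloyd_iterations: int = 10
    jitter_sigma_px: float = 0.0
    junction_width_px: float = 3.0
    background_margin_px: int = 0
    noise_sd: float = 0.02
    blur_sigma_px: float = 1.0
    rng_seed: int = 0
    interior_level: float = 0.12
    junction_level: float = 0.95
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("image must be at least 8x8 px")
        if self.junction_width_px <= 0:
            raise ValueError("junction_width_px must be positive")
        if self.junction_width_px >= min(self.width_px, self.height_px) / 4:
            raise ValueError("junction_width_px must be < min(width, height)/4")
        for name in ("lloyd_iterations", "background_margin_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("jitter_sigma_px", "noise_sd", "blur_sigma_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EpitheliumTruth:
    """Exact geometric ground truth for one generated image.

    ``cell_polygons`` are the Voronoi cells clipped to the foreground
    rectangle (shapely polygons, pixel coordinates, x = column, y = row).
    ``true_metrics`` holds per-cell area, perimeter, convex perimeter,
    convexity and geodesic diameter computed from the polygons (Voronoi
    cells are convex, so the geodesic diameter equals the ordinary
    diameter).  ``junction_mask`` is the rasterised junction band and
    ``owner_labels`` assigns every foreground pixel to its nearest seed
    (1-based; 0 = background margin).
    """

    cell_polygons: list
    true_metrics: pd.DataFrame
    junction_mask: np.ndarray
    owner_labels: np.ndarray
    seeds: np.ndarray
    spec: EpitheliumSpec = field(repr=False, default=None)


def _foreground_box(spec: EpitheliumSpec) -> tuple[float, float, float, float]:
    m = spec.background_margin_px
    return (m, m, spec.width_px - m, spec.height_px - m)


def _bounded_voronoi(seeds: np.ndarray, bounds) -> list[Polygon]:
    """Voronoi cells of `seeds` clipped to the bounding box, in seed order."""
    x0, y0, x1, y1 = bounds
    frame = box(x0, y0, x1, y1)
    if len(seeds) == 1:
        return [frame]
    cells = voronoi_diagram(MultiPoint([Point(p) for p in seeds]), envelope=frame)
    polys: list[Polygon] = [None] * len(seeds)
    raw = list(cells.geoms)
    # voronoi_diagram returns cells in arbitrary order; match by seed containment
    tree = shapely.STRtree(raw)
    for i, p in enumerate(seeds):
        pt = Point(p)
        for j in tree.query(pt):
            if raw[j].intersects(pt):
                polys[i] = raw[j].intersection(frame)
                break
        if polys[i] is None:  # numerically on an edge; fall back to scan
            polys[i] = min(raw, key=lambda g: g.distance(pt)).intersection(frame)
    return polys


def _lloyd_relax(seeds: np.ndarray, bounds, iterations: int) -> np.ndarray:
    for _ in range(iterations):
        polys = _bounded_voronoi(seeds, bounds)
        seeds = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    return seeds


def _polygon_metrics(polys: list[Polygon]) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(polys, start=1):
        hull = p.convex_hull
        verts = np.asarray(p.exterior.coords)
        # convex polygon: geodesic diameter == max pairwise vertex distance
        d = np.sqrt(((verts[:, None, :] - verts[None, :, :]) ** 2).sum(-1)).max()
        rows.append(
            {
                "cell_id": i,
                "area_px": p.area,
                "perimeter_px": p.length,
                "convex_perimeter_px": hull.length,
                "convexity": hull.length / p.length,
                "geodesic_diameter_px": d,
            }
        )
    return pd.DataFrame(rows)


def generate_epithelium(spec: EpitheliumSpec) -> tuple[np.ndarray, EpitheliumTruth]:
    """Render one synthetic junction image and its exact truth.

    Returns
    -------
    image : (H, W) uint16 array
        Junction band bright, interiors dark, blurred and noised.
    truth : EpitheliumTruth
    """
    rng = np.random.default_rng(spec.rng_seed)
    bounds = _foreground_box(spec)
    x0, y0, x1, y1 = bounds
    if x1 - x0 < 4 or y1 - y0 < 4:
        raise ValueError("background margin leaves no foreground")

    seeds = None
    for _attempt in range(spec.max_retries):
        cand = np.column_stack(
            [rng.uniform(x0 + 1, x1 - 1, spec.n_cells), rng.uniform(y0 + 1, y1 - 1, spec.n_cells)]
        )
        cand = _lloyd_relax(cand, bounds, spec.lloyd_iterations)
        if spec.jitter_sigma_px > 0:
            cand = cand + rng.normal(0.0, spec.jitter_sigma_px, cand.shape)
            cand[:, 0] = np.clip(cand[:, 0], x0 + 0.5, x1 - 0.5)
            cand[:, 1] = np.clip(cand[:, 1], y0 + 0.5, y1 - 0.5)
        if spec.n_cells == 1:
            seeds = cand
            break
        dmin = cKDTree(cand).query(cand, k=2)[0][:, 1].min()
        if dmin >= 2 * spec.junction_width_px:
            seeds = cand
            break
    if seeds is None:
        raise SeedCollisionError(
            f"seeds closer than 2*junction_width after {spec.max_retries} attempts"
        )

    polys = _bounded_voronoi(seeds, bounds)
    metrics = _polygon_metrics(polys)

    # rasterise: nearest-seed ownership + junction band where the two nearest
    # seeds are nearly equidistant (distance to the bisector ~ (d2 - d1)/2)
    H, W = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:H, 0:W]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    fg = (
        (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
    )
    owner = np.zeros(H * W, dtype=np.int32)
    band = np.zeros(H * W, dtype=bool)
    if spec.n_cells == 1:
        owner[fg] = 1
    else:
        dist, idx = cKDTree(seeds).query(pts[fg], k=2)
        owner[fg] = idx[:, 0] + 1
        band[fg] = (dist[:, 1] - dist[:, 0]) <= spec.junction_width_px
    owner = owner.reshape(H, W)
    band = band.reshape(H, W)
    fg = fg.reshape(H, W)

    # edge contact is defined at pixel level, on the cell interior the
    # measurement pipeline sees (owned pixels outside the junction band):
    # a cell touches the margin iff its interior reaches the foreground-
    # rectangle border, or it has no interior pixels at all
    ry0, ry1 = int(np.ceil(y0)), int(np.ceil(y1)) - 1
    rx0, rx1 = int(np.ceil(x0)), int(np.ceil(x1)) - 1
    interior = np.where(band, 0, owner)
    border_owner = set(
        np.unique(
            np.concatenate(
                [interior[ry0, rx0 : rx1 + 1], interior[ry1, rx0 : rx1 + 1],
                 interior[ry0 : ry1 + 1, rx0], interior[ry0 : ry1 + 1, rx1]]
            )
        )
    ) - {0}
    has_interior = set(np.unique(interior)) - {0}
    touching = border_owner | (set(range(1, spec.n_cells + 1)) - has_interior)
    metrics["touches_margin"] = metrics["cell_id"].isin(sorted(touching))

    base = np.zeros((H, W), dtype=float)
    base[fg] = spec.interior_level
    base[band] = spec.junction_level
    if spec.blur_sigma_px > 0:
        base = gaussian_filter(base, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, base.shape)
    image = (np.clip(base, 0.0, 1.0) * 65535).round().astype(np.uint16)

    truth = EpitheliumTruth(
        cell_polygons=polys,
        true_metrics=metrics,
        junction_mask=band,
        owner_labels=owner,
        seeds=seeds,
        spec=spec,
    )
    return image, truth
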