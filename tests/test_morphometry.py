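"""Segmentation and shape measurement against the generator's exact truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from rpekit import morphometry as M
from rpekit.synth import EpitheliumSpec, generate_epithelium

NOISE_FREE_CFG = M.MorphometryConfig(max_filter_radius_px=1, gaussian_sigma_px=1.0)


def test_preprocess_rejects_flat_image():
    with pytest.raises(ValueError, match="junction signal"):
        M.preprocess(np.zeros((64, 64)))


def test_preprocess_recovers_junction_band(small_epithelium):
    _, img, truth = small_epithelium
    mask = M.preprocess(img, M.MorphometryConfig(max_filter_radius_px=0, gaussian_sigma_px=0.5))
    band = truth.junction_mask
    inter = (mask & band).sum()
    assert inter / band.sum() >= 0.95  # mask covers the band
    assert inter / (mask | band).sum() >= 0.9  # and little more than the band


def test_binarization_is_fixed_point_up_to_filter_radius(small_epithelium):
    _, img, _ = small_epithelium
    cfg = M.MorphometryConfig(max_filter_radius_px=1, gaussian_sigma_px=0.0)
    mask = M.preprocess(img, cfg)
    mask2 = M.preprocess(mask.astype(float), cfg)
    n1 = ndi.label(~mask)[1]
    n2 = ndi.label(~mask2)[1]
    assert n1 == n2


def test_partition_of_single_line_gives_two_cells():
    mask = np.zeros((100, 100), dtype=bool)
    mask[50, :] = True
    lm = M.partition_cells(mask)
    assert lm.n_labels == 2
    # before junction reassignment the interiors cover everything but the line
    areas = np.bincount(lm.labels.ravel())[1:]
    assert areas.sum() == 100 * 100  # after reassignment: total partition


def test_partition_is_total_and_exclusive(small_epithelium):
    _, img, _ = small_epithelium
    lm = M.partition_cells(M.preprocess(img, NOISE_FREE_CFG), NOISE_FREE_CFG)
    assert (lm.labels > 0).all()  # every pixel has exactly one owner
    areas = np.bincount(lm.labels.ravel())
    assert areas[1:].sum() == lm.labels.size


def test_cell_count_matches_interior_truth(small_epithelium):
    _, img, truth = small_epithelium
    lm = M.partition_cells(M.preprocess(img, NOISE_FREE_CFG), NOISE_FREE_CFG)
    lm = M.postfilter_labels(lm, NOISE_FREE_CFG)
    n_interior = int((~truth.true_metrics.touches_margin).sum())
    assert lm.n_labels == n_interior


def test_postfilter_drops_border_labels_and_fills_holes():
    labels = np.zeros((60, 60), dtype=np.int32)
    labels[0:10, 0:10] = 1  # touches border -> dropped
    labels[20:40, 20:40] = 2
    labels[30, 30] = 0  # 1-px hole -> filled
    cfg = M.MorphometryConfig(label_dilation_px=0, min_cell_area_px=10)
    out = M.postfilter_labels(M.CellLabelMap(labels=labels), cfg)
    assert out.n_labels == 1
    assert (out.labels == 1).sum() == 400  # hole filled, renumbered to 1


def test_dilation_preserves_label_count(small_epithelium):
    """Dilation alone never merges or creates labels."""
    _, img, _ = small_epithelium
    lm = M.partition_cells(M.preprocess(img, NOISE_FREE_CFG), NOISE_FREE_CFG)
    for dil in (0, 1, 3):
        cfg = M.MorphometryConfig(label_dilation_px=dil, min_cell_area_px=0)
        interior = M.CellLabelMap(labels=np.where(lm.labels > 0, lm.labels, 0))
        out = M.postfilter_labels(interior, cfg)
        # only border removal may change the count, and it is dilation-independent
        border_labels = set(np.unique(np.concatenate([
            lm.labels[0], lm.labels[-1], lm.labels[:, 0], lm.labels[:, -1]
        ]))) - {0}
        assert out.n_labels == lm.n_labels - len(border_labels)


def test_square_label_area_and_1px_label_excluded():
    labels = np.zeros((30, 30), dtype=np.int32)
    labels[5:15, 5:15] = 1
    labels[20, 20] = 2
    rec = M.measure_shapes(M.CellLabelMap(labels=labels))
    square = rec[rec.cell_id == 1].iloc[0]
    assert square.area_px == 100
    assert not square.excluded
    assert rec[rec.cell_id == 2].iloc[0].excluded
    assert rec[rec.cell_id == 2].iloc[0].geodesic_diameter_px == 0.0


def test_disk_convexity_near_one():
    yy, xx = np.mgrid[0:80, 0:80]
    disk = ((yy - 40) ** 2 + (xx - 40) ** 2 <= 30**2).astype(np.int32)
    rec = M.measure_shapes(M.CellLabelMap(labels=disk))
    assert 0.95 <= rec.iloc[0].convexity <= 1.05


def test_pixel_size_conversion():
    labels = np.zeros((30, 30), dtype=np.int32)
    labels[5:15, 5:15] = 1
    rec = M.measure_shapes(M.CellLabelMap(labels=labels), pixel_size_um=0.5)
    assert rec.iloc[0].area_um2 == pytest.approx(100 * 0.25)


def test_distribution_summary_degenerate_and_normalised():
    rec = pd.DataFrame({"convexity": [0.9] * 10, "excluded": [False] * 10})
    d = M.summarize_distribution(rec, "convexity", bins=5)
    assert d["iqr"] == 0.0
    assert d["median"] == pytest.approx(0.9)
    assert d["frequencies"].sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        M.summarize_distribution(rec.assign(excluded=True), "convexity")


def test_compare_groups_requires_two_groups():
    rec = pd.DataFrame({"convexity": np.linspace(0.8, 1, 20), "excluded": False})
    d = M.summarize_distribution(rec, "convexity", group="only")
    with pytest.raises(ValueError):
        M.compare_groups([d])


def test_compare_groups_null_false_positive_rate():
    """Identical-population groups: rejections at alpha=0.05 stay near 5/100."""
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(100):
        a = rng.normal(0.95, 0.03, 60)
        b = rng.normal(0.95, 0.03, 60)
        da = {"group": "a", "values": a, "n": 60, "median": float(np.median(a)), "iqr": 0.0}
        db = {"group": "b", "values": b, "n": 60, "median": float(np.median(b)), "iqr": 0.0}
        hits += M.compare_groups([da, db])["significant"]
    assert hits <= 11  # expected 5; generous binomial envelope


def test_truth_recovery_on_noise_free_epithelium():
    """Measured metrics rank-correlate with polygon truth (rho >= 0.95)."""
    from scipy.stats import spearmanr
    from shapely.geometry import Point
    from skimage.measure import regionprops

    spec = EpitheliumSpec(
        width_px=640, height_px=640, n_cells=150, lloyd_iterations=5,
        jitter_sigma_px=6.0, noise_sd=0.0, blur_sigma_px=0.8, rng_seed=3,
    )
    img, truth = generate_epithelium(spec)
    lm = M.postfilter_labels(M.partition_cells(M.preprocess(img, NOISE_FREE_CFG), NOISE_FREE_CFG), NOISE_FREE_CFG)
    rec = M.measure_shapes(lm, config=NOISE_FREE_CFG)
    pairs = []
    for prop in regionprops(lm.labels):
        cy, cx = prop.centroid
        hit = [i for i, p in enumerate(truth.cell_polygons) if p.contains(Point(cx, cy))]
        if len(hit) == 1:
            pairs.append((prop.label, hit[0] + 1))
    match = pd.DataFrame(pairs, columns=["cell_id", "truth_id"])
    mm = rec.merge(match, on="cell_id").merge(
        truth.true_metrics, left_on="truth_id", right_on="cell_id", suffixes=("_m", "_t")
    )
    assert len(mm) >= 100
    assert spearmanr(mm.area_px_m, mm.area_px_t).statistic >= 0.95
    assert spearmanr(mm.geodesic_diameter_px_m, mm.geodesic_diameter_px_t).statistic >= 0.95
    # truth cells are convex: measured convexity deviates from 1 only by discretisation
    assert (mm.convexity_m - 1).abs().max() <= 0.05
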