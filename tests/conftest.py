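import numpy as np
import pytest

from rpekit.synth import (
    CountTableSpec,
    EpitheliumSpec,
    SpliceTableSpec,
    generate_count_table,
    generate_epithelium,
    generate_splice_table,
    make_de_stats,
    sample_groups,
)


@pytest.fixture(scope="session")
def small_epithelium():
    """Noise-free 256x256 monolayer with ~40 cells (shared, read-only)."""
    spec = EpitheliumSpec(
        width_px=256, height_px=256, n_cells=40, lloyd_iterations=5,
        jitter_sigma_px=0.0, noise_sd=0.0, blur_sigma_px=0.8, rng_seed=11,
    )
    return spec, *generate_epithelium(spec)


@pytest.fixture(scope="session")
def planted_count_table():
    """5,000-gene table with 300 genes up 8-fold in the affected group only."""
    spec = CountTableSpec(
        n_genes=5000,
        planted_sets=((tuple(range(300)), (0.0, 0.0, 3.0, 0.0)),),
        rng_seed=5,
    )
    counts, tpm, truth = generate_count_table(spec)
    groups = sample_groups(spec)
    stats = make_de_stats(
        tpm, groups, [("affected", "control"), ("affected", "asymptomatic")]
    )
    return spec, counts, tpm, truth, groups, stats


@pytest.fixture(scope="session")
def planted_splice_tables():
    """Three-comparison event tables with planted significant events.

    Planted |dPSI| = 0.35: indices 0..59 in affected-vs-control, 40..89 in
    affected-vs-carrier, 55..59 in carrier-vs-control, so the
    mutation-specific truth is {40..54}.
    """
    spec = SpliceTableSpec(
        n_events=800,
        mean_junction_depth=300,  # deep coverage: chance |dPSI|>0.1 is ~4 sigma
        planted_significant={
            "affected_vs_control": {i: 0.35 for i in range(60)},
            "affected_vs_carrier": {i: 0.35 for i in range(40, 90)},
            "carrier_vs_control": {i: 0.35 for i in range(55, 60)},
        },
        rng_seed=9,
    )
    tables, truth = generate_splice_table(spec)
    return spec, tables, truth


def rasterize_polygon(poly, shape):
    """Boolean mask of pixels whose integer coordinates fall inside `poly`."""
    import shapely
    from shapely.geometry import Point

    minx, miny, maxx, maxy = poly.bounds
    mask = np.zeros(shape, dtype=bool)
    xs = np.arange(max(0, int(np.floor(minx)) - 1), min(shape[1], int(np.ceil(maxx)) + 2))
    ys = np.arange(max(0, int(np.floor(miny)) - 1), min(shape[0], int(np.ceil(maxy)) + 2))
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]))
    inside = shapely.covers(poly, pts).reshape(yy.shape)
    mask[np.ix_(ys, xs)] = inside
    return mask
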