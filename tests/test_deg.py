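"""DEG filtering, z-scoring, clustering and mutation-specific selection."""

import numpy as np
import pandas as pd
import pytest

from rpekit import deg
from rpekit.synth import CountTableSpec, generate_count_table, sample_groups


def toy_tpm():
    tpm = pd.DataFrame(
        {
            "c_1": [0, 4.99, 10, 7, 3],
            "c_2": [0, 4.99, 12, 7, 3],
            "a_1": [5.0, 4.99, 11, 7, 3],
            "a_2": [0, 4.99, 10, 7, 3],
        },
        index=["g_boundary", "g_below", "g_high", "g_const", "g_low"],
    )
    groups = pd.Series(["ctrl", "ctrl", "aff", "aff"], index=tpm.columns, name="group")
    return tpm, groups


def test_tpm_filter_boundary_is_inclusive():
    tpm, groups = toy_tpm()
    kept = deg.tpm_filter(tpm, groups, tpm_min=5.0, mode="sample")
    assert "g_boundary" in kept  # a single sample at exactly 5.0 retains the gene
    assert "g_below" not in kept  # 4.99 everywhere is removed


def test_tpm_filter_group_mode_differs_from_sample_mode():
    tpm, groups = toy_tpm()
    by_group = deg.tpm_filter(tpm, groups, tpm_min=5.0, mode="group")
    # g_boundary: group means are (0, 2.5) -> fails in group mode
    assert "g_boundary" not in by_group
    with pytest.raises(ValueError):
        deg.tpm_filter(tpm, None, 5.0, mode="group")


def test_deg_filter_boundary_semantics():
    stats = pd.DataFrame(
        {
            "contrast": ["a_vs_b"] * 4,
            "gene_id": ["g1", "g2", "g3", "g4"],
            "log2fc": [1.0, 3.0, 0.99, -1.0],
            "pval": [0.001, 0.001, 0.001, 0.001],
            "fdr": [0.049, 0.2, 0.01, 0.05],
        }
    )
    out = deg.deg_filter(stats, deg.FilterConfig(), expressed={"g1", "g2", "g3", "g4"})
    # |log2FC| >= 1 inclusive; FDR < 0.05 strict
    assert out["a_vs_b"] == {"g1"}


def test_deg_filter_missing_column_names_contrast():
    stats = pd.DataFrame({"contrast": ["x"], "gene_id": ["g"], "log2fc": [1.0]})
    with pytest.raises(ValueError, match="x"):
        deg.deg_filter(stats, deg.FilterConfig())


def test_filters_match_bruteforce_predicate(planted_count_table):
    _, _, tpm, _, groups, stats = planted_count_table
    cfg = deg.FilterConfig()
    expressed = deg.tpm_filter(tpm, groups, cfg.tpm_min)
    sets = deg.deg_filter(stats, cfg, expressed)
    # independent row-scan oracle
    exp_oracle = {g for g in tpm.index if tpm.loc[g].max() >= cfg.tpm_min}
    assert expressed == exp_oracle
    for contrast, sub in stats.groupby("contrast"):
        oracle = {
            r.gene_id
            for r in sub.itertuples()
            if abs(r.log2fc) >= 1.0 and r.fdr < 0.05 and r.gene_id in exp_oracle
        }
        assert sets[str(contrast)] == oracle
    # idempotence / order-independence: same result from shuffled input
    shuffled = stats.sample(frac=1, random_state=0)
    assert deg.deg_filter(shuffled, cfg, expressed)["union"] == sets["union"]


def test_zscore_two_groups_population_sd():
    tpm = pd.DataFrame({"s1": [10.0], "s2": [100.0]}, index=["g"])
    groups = pd.Series(["g1", "g2"], index=tpm.columns)
    z = deg.zscore_profiles(tpm, groups)
    # population-SD convention: two distinct group means give exactly (-1, +1)
    assert np.allclose(sorted(z.loc["g"]), [-1.0, 1.0])


def test_zscore_constant_gene_dropped_and_normalised(planted_count_table):
    _, _, tpm, _, groups, _ = planted_count_table
    tpm2 = tpm.head(50).copy()
    tpm2.loc["g_const"] = 7.0
    z = deg.zscore_profiles(tpm2, groups)
    assert "g_const" not in z.index
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)


def test_cluster_separates_planted_archetypes():
    rng = np.random.default_rng(0)
    a = np.tile([2.0, -2.0, 0.0, 0.0], (30, 1)) + rng.normal(0, 0.05, (30, 4))
    b = np.tile([-2.0, 2.0, 0.0, 0.0], (30, 1)) + rng.normal(0, 0.05, (30, 4))
    z = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(60)])
    res = deg.cluster_genes(z, K=2)
    lab = res.assignments
    assert lab.iloc[:30].nunique() == 1 and lab.iloc[30:].nunique() == 1
    assert lab.iloc[0] != lab.iloc[-1]


def test_cluster_singletons_and_validation():
    z = pd.DataFrame(np.eye(4), index=list("abcd"))
    res = deg.cluster_genes(z, K=4)
    assert res.assignments.nunique() == 4
    with pytest.raises(ValueError):
        deg.cluster_genes(z, K=1)


def test_cluster_partition_invariant_under_row_permutation():
    rng = np.random.default_rng(1)
    z = pd.DataFrame(rng.normal(size=(80, 4)), index=[f"g{i}" for i in range(80)])
    res1 = deg.cluster_genes(z, K=6)
    res2 = deg.cluster_genes(z.sample(frac=1, random_state=3), K=6)

    def as_sets(r):
        return {frozenset(r.assignments.index[r.assignments == c]) for c in r.assignments.unique()}

    assert as_sets(res1) == as_sets(res2)


def test_select_clusters_margin_rule():
    z = pd.DataFrame(
        [[0.0, 0.0, 2.0, 0.0], [2.0, 0.0, 2.0, 0.0]],
        index=["specific", "shared"],
        columns=["ctrl", "asym", "aff", "iso"],
    )
    res = deg.ClusterResult(K=2, assignments=pd.Series([1, 2], index=z.index))
    sel = deg.select_clusters(res, z, "aff", ["ctrl", "asym", "iso"], delta=1.0)
    assert sel.selected == [1]  # the affected-only pattern
    assert sel.selected_genes == ["specific"]  # a control at +2 disqualifies
    with pytest.raises(ValueError):
        deg.select_clusters(res, z, "nope", ["ctrl"])


def test_selection_monotone_in_delta(planted_count_table):
    _, _, tpm, _, groups, stats = planted_count_table
    sizes = []
    for delta in (0.5, 1.0, 1.5, 2.0):
        res = deg.mutation_specific_genes(
            tpm, groups, stats, "affected", ["control", "asymptomatic", "isogenic"],
            K=15, delta=delta,
        )
        sizes.append(len(res["selected_genes"]))
    assert sizes == sorted(sizes, reverse=True)


def test_null_table_selects_almost_nothing():
    spec = CountTableSpec(n_genes=2000, rng_seed=21)
    _, tpm, _ = generate_count_table(spec)
    groups = sample_groups(spec)
    from rpekit.synth import make_de_stats

    stats = make_de_stats(tpm, groups, [("affected", "control"), ("affected", "asymptomatic")])
    res = deg.mutation_specific_genes(
        tpm, groups, stats, "affected", ["control", "asymptomatic", "isogenic"]
    )
    assert len(res["selected_genes"]) <= 0.05 * len(tpm)
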