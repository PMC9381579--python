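"""Splice-event parsing contract, filter semantics, and multi-comparison logic."""

import numpy as np
import pandas as pd
import pytest

from rpekit import splice as S


def make_event(**kw):
    base = dict(
        event_type="SE", gene_id="ENSG1", gene_symbol="SYN1", chrom="chr1",
        strand="+", coords=(100, 200, 10, 50, 300, 400),
        inc_counts_g1=[20, 25, 30], skip_counts_g1=[20, 25, 30],
        inc_counts_g2=[5, 6, 7], skip_counts_g2=[45, 44, 43],
        psi_g1=[0.5, 0.5, 0.5], psi_g2=[0.1, 0.12, 0.14],
        inc_level_difference=0.38, pvalue=1e-5, fdr=1e-4,
    )
    base.update(kw)
    return base


def table_of(*events):
    df = pd.DataFrame(list(events))
    df["key"] = [S.event_key(r) for r in df.itertuples(index=False)]
    return df


def test_parse_psi_list_with_missing(tmp_path):
    df = table_of(make_event(psi_g1=[0.9, 0.85, np.nan]))
    p = tmp_path / "SE.MATS.JC.txt"
    S.write_rmats_file(df, p, "SE")
    assert "0.900,0.850,NA" in p.read_text()
    back = S.read_rmats_file(p, "SE")
    got = back.iloc[0].psi_g1
    assert got[0] == 0.9 and got[1] == 0.85 and np.isnan(got[2])


def test_empty_file_with_header_is_empty_table(tmp_path):
    df = table_of(make_event()).iloc[:0]
    p = tmp_path / "SE.MATS.JC.txt"
    S.write_rmats_file(df, p, "SE")
    back = S.read_rmats_file(p, "SE")
    assert len(back) == 0


def test_malformed_row_reports_line(tmp_path):
    df = table_of(make_event())
    p = tmp_path / "SE.MATS.JC.txt"
    S.write_rmats_file(df, p, "SE")
    text = p.read_text().splitlines()
    text[1] = text[1].replace("100", "not_an_int", 1)
    p.write_text("\n".join(text))
    with pytest.raises(ValueError, match=":2"):
        S.read_rmats_file(p, "SE")


def test_filter_keeps_clear_event_and_enforces_strict_boundaries():
    cfg = S.SelectionConfig()
    clear = make_event()
    at_dpsi = make_event(inc_level_difference=0.10, psi_g2=[0.4, 0.4, 0.4])
    at_fdr = make_event(fdr=0.05)
    low_count = make_event(
        inc_counts_g1=[1, 0, 0], skip_counts_g1=[0, 1, 0],
        inc_counts_g2=[0, 0, 1], skip_counts_g2=[1, 0, 0],
    )
    low_psi = make_event(psi_g1=[0.05] * 3, psi_g2=[0.01] * 3, inc_level_difference=0.04)
    out = S.significant_events(table_of(clear, at_dpsi, at_fdr, low_count, low_psi), cfg)
    assert len(out) == 1 and out.iloc[0].fdr == 1e-4
    # dPSI == 0.10 exactly is dropped: "more than 10%" is strict; so is FDR < 0.05


def test_min_count_boundary_inclusive():
    cfg = S.SelectionConfig()
    ev = make_event(
        inc_counts_g1=[1, 0, 0], skip_counts_g1=[1, 0, 0],
        inc_counts_g2=[0, 0, 0], skip_counts_g2=[1, 1, 1],
    )  # best sample has inc+skip == 2
    assert len(S.significant_events(table_of(ev), cfg)) == 1


def test_filter_matches_bruteforce_enumeration(planted_splice_tables):
    _, tables, _ = planted_splice_tables
    cfg = S.SelectionConfig()
    for df in tables.values():
        kept = set(S.significant_events(df, cfg)["key"])
        oracle = set()
        for r in df.itertuples(index=False):
            m1, m2 = np.nanmean(r.psi_g1), np.nanmean(r.psi_g2)
            counts = [a + b for a, b in zip(r.inc_counts_g1, r.skip_counts_g1)]
            counts += [a + b for a, b in zip(r.inc_counts_g2, r.skip_counts_g2)]
            if (
                max(counts) >= 2
                and r.fdr < 0.05
                and abs(r.inc_level_difference) > 0.10
                and max(m1, m2) >= 0.10
            ):
                oracle.add(r.key)
        assert kept == oracle


def test_tightening_thresholds_never_grows_selection(planted_splice_tables):
    _, tables, _ = planted_splice_tables
    df = tables["affected_vs_control"]
    base = set(S.significant_events(df, S.SelectionConfig())["key"])
    for tighter in (
        S.SelectionConfig(min_delta_psi=0.2),
        S.SelectionConfig(alpha_fdr=0.01),
        S.SelectionConfig(min_count=10),
        S.SelectionConfig(min_psi=0.3),
    ):
        assert set(S.significant_events(df, tighter)["key"]) <= base


def test_tpm_floor_requires_expression_table():
    with pytest.raises(ValueError, match="expression"):
        S.significant_events(table_of(make_event()), S.SelectionConfig(tpm_min=5.0))


def test_intersection_set_algebra():
    e1, e2, e3 = (make_event(coords=(100 * k, 200, 10, 50, 300, 400)) for k in (1, 2, 3))
    A, B, C = table_of(e1, e2), table_of(e2, e3), table_of(e2)
    assert len(S.intersect_mutation_specific([A, B], [C])) == 0
    out = S.intersect_mutation_specific([A, B], [table_of(e1).iloc[:0]])
    assert list(out["key"]) == [S.event_key(pd.DataFrame([e2]).iloc[0])]
    # two-set mode: single include, nothing excluded
    assert len(S.intersect_mutation_specific([A])) == 2


def test_intersection_invariant_to_order_and_duplicates():
    e1, e2 = (make_event(coords=(100 * k, 200, 10, 50, 300, 400)) for k in (1, 2))
    A = table_of(e1, e2)
    A_dup = table_of(e2, e1, e1)
    B = table_of(e2, e1)
    r1 = S.intersect_mutation_specific([A, B])
    r2 = S.intersect_mutation_specific([A_dup, B])
    assert set(r1["key"]) == set(r2["key"])


def test_intersection_recovers_planted_truth(planted_splice_tables):
    _, tables, truth = planted_splice_tables
    cfg = S.SelectionConfig()
    sig = {c: S.significant_events(t, cfg) for c, t in tables.items()}
    res = S.intersect_mutation_specific(
        [sig["affected_vs_control"], sig["affected_vs_carrier"]],
        [sig["carrier_vs_control"]],
    )
    expect = (
        set(truth["affected_vs_control"].index[truth["affected_vs_control"]])
        & set(truth["affected_vs_carrier"].index[truth["affected_vs_carrier"]])
        - set(truth["carrier_vs_control"].index[truth["carrier_vs_control"]])
    )
    assert set(res["key"]) == expect


def test_composition_counts_and_unique_genes():
    evs = [make_event(coords=(i, 200, 10, 50, 300, 400), gene_id=f"ENSG{i%3}") for i in range(7)]
    evs += [make_event(event_type="MXE", coords=(i, 2, 3, 4, 5, 6, 7, 8)) for i in range(7)]
    comp = S.composition(table_of(*evs))
    assert comp["counts"]["SE"] == 7 and comp["counts"]["MXE"] == 7
    assert comp["percentages"]["SE"] == pytest.approx(50.0)
    assert sum(comp["percentages"].values()) == pytest.approx(100.0, abs=0.1)
    se_only = table_of(*evs[:7])
    assert S.composition(se_only)["n_unique_genes"] == 3
    empty = S.composition(se_only.iloc[:0])
    assert empty["n_events"] == 0 and empty["n_unique_genes"] == 0
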