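"""End-to-end orchestration: synthetic inputs -> all analysis stages -> report.

One ``RunConfig`` drives the stage DAG (synthetic -> {morphometry, deg,
splice, assay} -> report).  Every stage writes its tables plus a JSON
manifest entry (config hash, derived seed, row counts), and the demo mode
generates everything synthetically so a full run needs no external data.
Stage seeds are derived from the global seed by hashing the stage name, so
stages are independent but the whole run is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import assays as A
from . import deg as D
from . import morphometry as M
from . import splice as S
from .synth import (
    CountTableSpec,
    EpitheliumSpec,
    SpliceTableSpec,
    generate_assay_fixtures,
    generate_count_table,
    generate_epithelium,
    generate_splice_table,
    make_de_stats,
    sample_groups,
)

logger = logging.getLogger(__name__)

STAGES = ("synthetic", "morphometry", "deg", "splice", "assay")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = STAGES
    rng_seed: int = 0
    epithelium: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    splice_tables: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    deg: dict = field(default_factory=dict)
    splice: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent per-stage seed: global seed mixed with the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _hash_config(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in config.__dict__.items() if k not in ("out_dir", "log_level")}
    manifest: dict = {
        "config_hash": _hash_config(hashed),
        "rng_seed": config.rng_seed,
        "stages": {},
    }
    artefacts: dict = {}
    for stage in config.stages:
        try:
            runner = _STAGE_RUNNERS[stage]
            entry = runner(config, out, artefacts)
        except Exception as exc:  # noqa: BLE001 — abort with named stage
            _write_json(out / "manifest.json", manifest)
            raise StageError(stage, exc) from exc
        entry["seed"] = stage_seed(config.rng_seed, stage)
        manifest["stages"][stage] = entry
    _write_json(out / "manifest.json", manifest)
    return manifest


def _run_synthetic(config: RunConfig, out: Path, art: dict) -> dict:
    seed = stage_seed(config.rng_seed, "synthetic")
    espec = EpitheliumSpec(**{"rng_seed": seed, **config.epithelium})
    image, truth = generate_epithelium(espec)
    tifffile.imwrite(out / "epithelium.tif", image, photometric="minisblack")
    truth.true_metrics.to_csv(out / "epithelium_truth.tsv", sep="\t", index=False)

    cspec = CountTableSpec(**{"rng_seed": seed + 1, **config.counts})
    counts, tpm, ctruth = generate_count_table(cspec)
    groups = sample_groups(cspec)
    counts.to_csv(out / "counts.tsv", sep="\t")
    tpm.to_csv(out / "tpm.tsv", sep="\t")
    groups.to_csv(out / "groups.tsv", sep="\t")
    contrasts = [(g, h) for g in ["affected"] for h in cspec.groups if h != "affected"]
    stats = make_de_stats(tpm, groups, contrasts)
    stats.to_csv(out / "de_stats.tsv", sep="\t", index=False)

    sspec = SpliceTableSpec(**{"rng_seed": seed + 2, **config.splice_tables})
    tables, struth = generate_splice_table(sspec)
    for label, df in tables.items():
        d = out / f"rmats_{label}"
        d.mkdir(exist_ok=True)
        for et in S.EVENT_TYPES:
            S.write_rmats_file(df, d / f"{et}.MATS.JC.txt", et)

    fixtures = generate_assay_fixtures(seed + 3)
    for name, tab in fixtures.items():
        tab.to_csv(out / f"assay_{name}.csv", index=False)

    art.update(
        image=image, truth=truth, counts=counts, tpm=tpm, groups=groups,
        de_stats=stats, splice_tables=tables, splice_truth=struth,
        fixtures=fixtures, count_spec=cspec, splice_spec=sspec,
    )
    return {
        "epithelium": {"cells": len(truth.cell_polygons), "shape": list(image.shape)},
        "counts": {"genes": len(counts), "samples": counts.shape[1]},
        "splice": {c: len(t) for c, t in tables.items()},
        "assays": {k: len(v) for k, v in fixtures.items()},
    }


def _run_morphometry(config: RunConfig, out: Path, art: dict) -> dict:
    if "image" not in art:
        image = tifffile.imread(out / "epithelium.tif")
    else:
        image = art["image"]
    cfg = M.MorphometryConfig(**config.morphometry)
    mask = M.preprocess(image, cfg)
    labelmap = M.postfilter_labels(M.partition_cells(mask, cfg), cfg)
    records = M.measure_shapes(labelmap, config=cfg)
    records.to_csv(out / "cell_shapes.tsv", sep="\t", index=False)
    dist = M.summarize_distribution(records, "convexity", bins=20, group="demo")
    pd.DataFrame(
        {
            "bin_left": dist["bin_edges"][:-1],
            "bin_right": dist["bin_edges"][1:],
            "count": dist["counts"],
            "frequency": dist["frequencies"],
        }
    ).to_csv(out / "convexity_distribution.tsv", sep="\t", index=False)
    return {
        "cells_measured": int(len(records)),
        "median_convexity": round(dist["median"], 6),
        "convexity_iqr": round(dist["iqr"], 6),
        "config": cfg.to_dict(),
    }


def _run_deg(config: RunConfig, out: Path, art: dict) -> dict:
    tpm = art.get("tpm")
    if tpm is None:
        tpm = pd.read_csv(out / "tpm.tsv", sep="\t", index_col=0)
        art["groups"] = pd.read_csv(out / "groups.tsv", sep="\t", index_col=0)["group"]
        art["de_stats"] = pd.read_csv(out / "de_stats.tsv", sep="\t")
    groups = art["groups"]
    stats = art["de_stats"]
    opts = dict(config.deg)
    fc = D.FilterConfig(
        **{k: v for k, v in opts.items() if k in ("fc_min", "alpha", "alpha_column", "tpm_min", "tpm_mode")}
    )
    res = D.mutation_specific_genes(
        tpm,
        groups,
        stats,
        affected_group=opts.get("affected_group", "affected"),
        control_groups=opts.get("control_groups", [g for g in dict.fromkeys(groups) if g != "affected"]),
        config=fc,
        K=opts.get("K", 15),
        delta=opts.get("delta", 1.0),
    )
    for contrast, genes in res["degs"].items():
        pd.Series(sorted(genes), name="gene_id").to_csv(
            out / f"degs_{contrast}.tsv", sep="\t", index=False
        )
    if res["clusters"] is not None:
        res["clusters"].assignments.to_csv(out / "clusters.tsv", sep="\t")
    pd.Series(res["selected_genes"], name="gene_id").to_csv(
        out / "selected_genes.tsv", sep="\t", index=False
    )
    entry = {
        "degs_per_contrast": {c: len(g) for c, g in res["degs"].items()},
        "selected_clusters": res["clusters"].selected if res["clusters"] else [],
        "selected_genes": len(res["selected_genes"]),
    }
    _write_json(out / "deg_summary.json", entry)
    return entry


def _run_splice(config: RunConfig, out: Path, art: dict) -> dict:
    tables = art.get("splice_tables")
    if tables is None:
        tables = {}
        for d in sorted(out.glob("rmats_*")):
            label = d.name.removeprefix("rmats_")
            tables[label] = S.read_rmats({et: d / f"{et}.MATS.JC.txt" for et in S.EVENT_TYPES})
    opts = dict(config.splice)
    cfg = S.SelectionConfig(
        **{k: v for k, v in opts.items() if k in ("min_psi", "min_delta_psi", "alpha_fdr", "min_count", "tpm_min", "psi_mode")}
    )
    include_labels = opts.get("include", list(tables)[:2])
    exclude_labels = opts.get("exclude", list(tables)[2:3])
    sig = {c: S.significant_events(t, cfg) for c, t in tables.items()}
    result = S.intersect_mutation_specific(
        [sig[c] for c in include_labels], [sig[c] for c in exclude_labels]
    )
    comp = S.composition(result)
    result.drop(columns=["key"]).to_csv(out / "selected_events.tsv", sep="\t", index=False)
    entry = {
        "significant_per_comparison": {c: int(len(t)) for c, t in sig.items()},
        "include": list(include_labels),
        "exclude": list(exclude_labels),
        **comp,
    }
    _write_json(out / "splice_composition.json", entry)
    return entry


def _run_assay(config: RunConfig, out: Path, art: dict) -> dict:
    fixtures = art.get("fixtures")
    if fixtures is None:
        fixtures = {
            name: pd.read_csv(out / f"assay_{name}.csv")
            for name in ("ter", "phagocytosis", "western", "counting", "qpcr")
        }
    results: dict = {}

    ter = fixtures["ter"].copy()
    ter["ter_ohm_cm2"] = A.ter_normalize(ter.raw_ohm, ter.blank_ohm, ter.area_cm2)
    ter.to_csv(out / "ter_quantified.csv", index=False)
    results["ter"] = A.group_test({g: v.ter_ohm_cm2.to_numpy() for g, v in ter.groupby("group")})

    ph = fixtures["phagocytosis"].copy()
    internal, bound = A.phagocytosis_ratios(ph.total_fitc, ph.quenched_fitc, ph.dapi)
    ph["internalized_ratio"], ph["bound_ratio"] = internal, bound
    ph.to_csv(out / "phagocytosis_quantified.csv", index=False)
    results["phagocytosis"] = A.group_test({g: v.internalized_ratio.to_numpy() for g, v in ph.groupby("group")})

    wb = fixtures["western"].copy()
    ref_mean = (wb.loc[wb.group == "control", "target_band"] / wb.loc[wb.group == "control", "loading_band"]).mean()
    wb["ratio"], wb["fold"] = A.band_ratio_fold(wb.target_band, wb.loading_band, ref_mean)
    wb.to_csv(out / "western_quantified.csv", index=False)
    results["western"] = A.group_test({g: v.fold.to_numpy() for g, v in wb.groupby("group")})

    ct = fixtures["counting"].copy()
    ct["marker_pct"] = A.marker_fraction(ct.n_marker, ct.n_dapi)
    ct["density_per_mm2"] = A.onl_density(ct.n_dapi, ct.region_area_mm2)
    ct.to_csv(out / "counting_quantified.csv", index=False)
    results["counting"] = A.group_test({g: v.marker_pct.to_numpy() for g, v in ct.groupby("group")})

    qp = fixtures["qpcr"].copy()
    dct = qp.ct_target - qp.ct_housekeeping
    ref_dct = dct[qp.group == "control"].mean()
    qp["fold"] = A.dct_fold(qp.ct_target, qp.ct_housekeeping, ref_dct)
    qp.to_csv(out / "qpcr_quantified.csv", index=False)
    results["qpcr"] = A.group_test({g: v.fold.to_numpy() for g, v in qp.groupby("group")})

    entry = {
        name: {
            "pvalue": round(r["pvalue"], 8),
            "significant": r["significant"],
            "groups": {g: {"n": s["n"], "mean": round(s["mean"], 4)} for g, s in r["group_summary"].items()},
        }
        for name, r in results.items()
    }
    _write_json(out / "assay_summary.json", entry)
    return entry


_STAGE_RUNNERS = {
    "synthetic": _run_synthetic,
    "morphometry": _run_morphometry,
    "deg": _run_deg,
    "splice": _run_splice,
    "assay": _run_assay,
}


def demo(seed: int, out_dir: str | Path) -> dict:
    """Full synthetic demonstration run (all stages, default sizes)."""
    planted = tuple(range(300))
    cfg = RunConfig(
        out_dir=str(out_dir),
        rng_seed=seed,
        counts={"planted_sets": ((planted, (0.0, 0.0, 3.0, 0.0)),)},
        splice_tables={
            "planted_significant": {
                "affected_vs_control": {i: 0.35 for i in range(60)},
                "affected_vs_carrier": {i: 0.35 for i in range(40, 90)},
                "carrier_vs_control": {i: 0.35 for i in range(55, 60)},
            }
        },
    )
    return run_pipeline(cfg)
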