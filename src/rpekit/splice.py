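"""rMATS-style alternative-splicing event tables: parsing, filtering, set logic.

Event tables follow the rMATS junction-count (``*.MATS.JC.txt``) dialect:
one tab-delimited file per event type (SE, MXE, RI, A5SS, A3SS) and per
group comparison, with per-replicate inclusion/skipping junction counts,
per-replicate PSI (percent spliced in) lists, the between-group PSI
difference, and p/FDR columns.  This module parses those files into one
tidy table, applies the significance filters (junction-count floor, FDR,
|dPSI|, minimum PSI, optional expression floor), and intersects the
filtered sets across comparisons to isolate events specific to the
affected genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "MXE", "RI", "A5SS", "A3SS")

EVENT_TYPE_NAMES = {
    "SE": "skipped exon",
    "MXE": "mutually exclusive exons",
    "RI": "retained intron",
    "A5SS": "alternative 5' splice site",
    "A3SS": "alternative 3' splice site",
}

# rMATS coordinate columns per event type: 0-based starts, 1-based ends
COORD_COLUMNS = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
    "MXE": [
        "1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    ],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE", "flankingES", "flankingEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE", "flankingES", "flankingEE"],
}

_COMMON = ["ID", "GeneID", "geneSymbol", "chr", "strand"]
_STATS = [
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen", "PValue", "FDR",
    "IncLevel1", "IncLevel2", "IncLevelDifference",
]


class EventKey(NamedTuple):
    """Identity of one splicing event across comparisons: exact coordinates."""

    event_type: str
    chrom: str
    strand: str
    coords: tuple
    gene_id: str


@dataclass(frozen=True)
class SelectionConfig:
    """Significance thresholds for splice-event selection.

    min_count (inclusive) applies to the per-sample sum of inclusion and
    skipping junction reads, maximised over samples; alpha_fdr and
    min_delta_psi are strict (< 0.05, > 0.10); min_psi (inclusive) demands
    that at least one group's mean PSI reaches the floor, i.e. the event is
    actually included somewhere; tpm_min, when set, additionally requires
    the host gene's best group-mean TPM to reach the floor.
    """

    min_psi: float = 0.10
    min_delta_psi: float = 0.10
    alpha_fdr: float = 0.05
    min_count: int = 2
    tpm_min: float | None = None
    psi_mode: str = "max_group"  # or "both_within" (both means in [min_psi, 1-min_psi])

    def __post_init__(self) -> None:
        for name in ("min_psi", "min_delta_psi", "alpha_fdr"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.psi_mode not in ("max_group", "both_within"):
            raise ValueError("psi_mode must be 'max_group' or 'both_within'")

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_int_list(s: str) -> list[int]:
    return [int(x) for x in str(s).split(",") if x != ""]


def _parse_psi_list(s: str) -> list[float]:
    return [np.nan if x == "NA" else float(x) for x in str(s).split(",") if x != ""]


def _fmt_psi_list(vals: Iterable[float]) -> str:
    return ",".join("NA" if not np.isfinite(v) else f"{v:0.3f}" for v in vals)


def read_rmats_file(path: str | Path, event_type: str) -> pd.DataFrame:
    """Parse one rMATS JC file into tidy rows (one event per row)."""
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    needed = set(_COMMON + COORD_COLUMNS[event_type] + _STATS) - {"ID"}
    missing = needed - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for lineno, (_, r) in enumerate(raw.iterrows(), start=2):
        try:
            coords = tuple(int(r[c]) for c in COORD_COLUMNS[event_type])
            inc1 = _parse_int_list(r["IJC_SAMPLE_1"])
            skip1 = _parse_int_list(r["SJC_SAMPLE_1"])
            inc2 = _parse_int_list(r["IJC_SAMPLE_2"])
            skip2 = _parse_int_list(r["SJC_SAMPLE_2"])
            psi1 = _parse_psi_list(r["IncLevel1"])
            psi2 = _parse_psi_list(r["IncLevel2"])
            rows.append(
                {
                    "event_type": event_type,
                    "gene_id": r["GeneID"],
                    "gene_symbol": r["geneSymbol"],
                    "chrom": r["chr"],
                    "strand": r["strand"],
                    "coords": coords,
                    "inc_counts_g1": inc1,
                    "skip_counts_g1": skip1,
                    "inc_counts_g2": inc2,
                    "skip_counts_g2": skip2,
                    "psi_g1": psi1,
                    "psi_g2": psi2,
                    "inc_level_difference": float(r["IncLevelDifference"]),
                    "pvalue": float(r["PValue"]),
                    "fdr": float(r["FDR"]),
                }
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    df = pd.DataFrame(
        rows,
        columns=[
            "event_type", "gene_id", "gene_symbol", "chrom", "strand", "coords",
            "inc_counts_g1", "skip_counts_g1", "inc_counts_g2", "skip_counts_g2",
            "psi_g1", "psi_g2", "inc_level_difference", "pvalue", "fdr",
        ],
    )
    if len(df):
        df["key"] = [event_key(r) for r in df.itertuples(index=False)]
    else:
        df["key"] = pd.Series(dtype=object)
    return df


def read_rmats(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Parse one comparison: mapping event type -> JC file path."""
    frames = [read_rmats_file(p, et) for et, p in paths.items()]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def write_rmats_file(df: pd.DataFrame, path: str | Path, event_type: str) -> None:
    """Serialise tidy rows of one event type back to the JC dialect."""
    sub = df[df["event_type"] == event_type]
    out = pd.DataFrame()
    out["ID"] = np.arange(len(sub))
    out["GeneID"] = sub["gene_id"].to_numpy()
    out["geneSymbol"] = sub["gene_symbol"].to_numpy()
    out["chr"] = sub["chrom"].to_numpy()
    out["strand"] = sub["strand"].to_numpy()
    for i, c in enumerate(COORD_COLUMNS[event_type]):
        out[c] = [co[i] for co in sub["coords"]]
    out["ID.1"] = out["ID"]
    out["IJC_SAMPLE_1"] = [",".join(map(str, v)) for v in sub["inc_counts_g1"]]
    out["SJC_SAMPLE_1"] = [",".join(map(str, v)) for v in sub["skip_counts_g1"]]
    out["IJC_SAMPLE_2"] = [",".join(map(str, v)) for v in sub["inc_counts_g2"]]
    out["SJC_SAMPLE_2"] = [",".join(map(str, v)) for v in sub["skip_counts_g2"]]
    out["IncFormLen"] = 2
    out["SkipFormLen"] = 1
    out["PValue"] = sub["pvalue"].to_numpy()
    out["FDR"] = sub["fdr"].to_numpy()
    out["IncLevel1"] = [_fmt_psi_list(v) for v in sub["psi_g1"]]
    out["IncLevel2"] = [_fmt_psi_list(v) for v in sub["psi_g2"]]
    out["IncLevelDifference"] = sub["inc_level_difference"].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def event_key(row) -> EventKey:
    return EventKey(
        event_type=row.event_type,
        chrom=row.chrom,
        strand=row.strand,
        coords=tuple(row.coords),
        gene_id=row.gene_id,
    )


def _mean_psi(vals: list[float]) -> float:
    arr = np.asarray(vals, dtype=float)
    finite = arr[np.isfinite(arr)]
    return float(finite.mean()) if len(finite) else np.nan


def significant_events(
    table: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
    tpm: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Rows of `table` passing every selection predicate.

    Predicates (conjunction): junction support (max per-sample inc+skip
    count >= min_count), FDR < alpha_fdr, |dPSI| > min_delta_psi, mean PSI
    floor per psi_mode, and optionally host-gene TPM.  Events whose PSI is
    missing in an entire group are dropped and counted in the log.
    """
    if config.tpm_min is not None and tpm is None:
        raise ValueError("tpm_min is set but no expression table was supplied")
    if len(table) == 0:
        return table.copy()
    keep = np.ones(len(table), dtype=bool)
    n_all_missing = 0
    gene_ok: dict[str, bool] = {}
    if config.tpm_min is not None:
        if groups is not None:
            order = list(dict.fromkeys(groups))
            gmeans = pd.DataFrame(
                {g: tpm.loc[:, groups.index[groups == g]].mean(axis=1) for g in order}
            ).max(axis=1)
        else:
            gmeans = tpm.max(axis=1)
        gene_ok = (gmeans >= config.tpm_min).to_dict()
    for i, row in enumerate(table.itertuples(index=False)):
        m1, m2 = _mean_psi(row.psi_g1), _mean_psi(row.psi_g2)
        if not np.isfinite(m1) or not np.isfinite(m2):
            n_all_missing += 1
            keep[i] = False
            continue
        counts = [a + b for a, b in zip(row.inc_counts_g1, row.skip_counts_g1)]
        counts += [a + b for a, b in zip(row.inc_counts_g2, row.skip_counts_g2)]
        ok = max(counts) >= config.min_count
        ok &= row.fdr < config.alpha_fdr
        ok &= abs(row.inc_level_difference) > config.min_delta_psi
        if config.psi_mode == "max_group":
            ok &= max(m1, m2) >= config.min_psi
        else:
            ok &= (config.min_psi <= m1 <= 1 - config.min_psi) and (
                config.min_psi <= m2 <= 1 - config.min_psi
            )
        if config.tpm_min is not None:
            ok &= bool(gene_ok.get(row.gene_id, False))
        keep[i] = ok
    if n_all_missing:
        logger.info("significant_events: dropped %d event(s) with a PSI-less group", n_all_missing)
    return table.loc[keep].reset_index(drop=True)


def _dedupe(table: pd.DataFrame) -> pd.DataFrame:
    dup = table["key"].duplicated()
    if dup.any():
        logger.warning("collapsing %d duplicate event key(s)", int(dup.sum()))
    return table.loc[~dup]


def intersect_mutation_specific(
    include: list[pd.DataFrame],
    exclude: list[pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Events present in every `include` comparison and absent from every
    `exclude` comparison: (A ∩ B ∩ ...) \\ (C ∪ ...).

    The three-comparison design (affected-vs-control ∩ affected-vs-carrier,
    minus carrier-vs-control) isolates events tied to the disease genotype;
    the two-set organoid mode passes a single include table and no exclude.
    Rows are returned from the first include table; duplicates and row
    order do not affect the result.
    """
    if not include:
        raise ValueError("need at least one comparison to intersect")
    include = [_dedupe(t) for t in include]
    keys = set(include[0]["key"])
    for t in include[1:]:
        keys &= set(t["key"])
    for t in exclude or []:
        keys -= set(t["key"])
    base = include[0]
    out = base.loc[base["key"].isin(keys)].reset_index(drop=True)
    return out


def composition(events: pd.DataFrame) -> dict:
    """Event-type counts/percentages and the number of distinct host genes."""
    counts = {et: 0 for et in EVENT_TYPES}
    if len(events):
        for et, c in events["event_type"].value_counts().items():
            counts[str(et)] = int(c)
    total = sum(counts.values())
    pct = {et: (100.0 * c / total if total else 0.0) for et, c in counts.items()}
    return {
        "n_events": total,
        "n_unique_genes": int(events["gene_id"].nunique()) if len(events) else 0,
        "counts": counts,
        "percentages": pct,
    }
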