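"""Synthetic rMATS-dialect splice-event tables with planted significant events.

Each comparison gets the same catalogue of events (shared identity across
comparisons, so set logic is meaningful).  Per replicate, junction depth is
Poisson around a mean and inclusion reads are binomial around the group
PSI; p-values come from a two-proportion z-test on the summed junction
counts and are BH-adjusted within the comparison.  Planted events carry a
group-2 PSI shifted by the requested delta; everything else shares one PSI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..splice import EVENT_TYPES, EventKey

DEFAULT_TYPE_MIX = {"SE": 0.50, "MXE": 0.22, "RI": 0.10, "A5SS": 0.09, "A3SS": 0.09}


@dataclass(frozen=True)
class SpliceTableSpec:
    """Design of synthetic per-comparison event tables.

    planted_significant maps a comparison label to {event index: target
    |dPSI|}; those events get a shifted group-2 PSI in that comparison.
    """

    n_events: int = 2000
    type_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    comparisons: tuple[str, ...] = ("affected_vs_control", "affected_vs_carrier", "carrier_vs_control")
    planted_significant: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    reps_per_side: int = 3
    mean_junction_depth: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1 or self.reps_per_side < 1:
            raise ValueError("n_events and reps_per_side must be positive")
        if self.mean_junction_depth <= 0:
            raise ValueError("mean_junction_depth must be positive")
        if set(self.type_mix) - set(EVENT_TYPES):
            raise ValueError("type_mix has unknown event types")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        for cmp_label, planted in self.planted_significant.items():
            if cmp_label not in self.comparisons:
                raise ValueError(f"unknown comparison {cmp_label!r}")
            for idx, d in planted.items():
                if not 0 < d <= 1:
                    raise ValueError("planted |dPSI| must be in (0, 1]")
                if not 0 <= idx < self.n_events:
                    raise ValueError("planted event index out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["type_mix"] = dict(self.type_mix)
        d["planted_significant"] = {k: dict(v) for k, v in self.planted_significant.items()}
        return d


def _event_coords(rng: np.random.Generator, event_type: str, anchor: int) -> tuple:
    """Plausible rMATS coordinates (0-based starts, 1-based ends, half-open)."""
    exon = lambda s: (s, s + int(rng.integers(60, 300)))
    up = exon(anchor)
    mid1 = exon(up[1] + int(rng.integers(200, 2000)))
    mid2 = exon(mid1[1] + int(rng.integers(200, 2000)))
    down = exon(mid2[1] + int(rng.integers(200, 2000)))
    if event_type == "SE":
        return (*mid1, *up, *down)
    if event_type == "MXE":
        return (*mid1, *mid2, *up, *down)
    if event_type == "RI":
        return (up[0], mid1[1], *up, *mid1)
    # A5SS / A3SS: long exon extends past the short one
    short = mid1
    long = (short[0] - int(rng.integers(30, 120)), short[1]) if event_type == "A3SS" else (short[0], short[1] + int(rng.integers(30, 120)))
    return (*long, *short, *down)


def generate_splice_table(
    spec: SpliceTableSpec,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.Series]]:
    """Per-comparison tidy event tables plus per-comparison truth flags.

    Returns (tables, truth): tables[label] is a tidy DataFrame as produced
    by :func:`rpekit.splice.read_rmats`; truth[label] is a boolean Series
    over event keys marking the planted-significant events.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_events
    types = rng.choice(
        list(spec.type_mix), size=n, p=np.array(list(spec.type_mix.values()))
    )
    chroms = rng.choice([f"chr{i}" for i in range(1, 23)], size=n)
    strands = rng.choice(["+", "-"], size=n)
    anchors = rng.integers(10_000, 5_000_000, size=n)
    base_psi = rng.uniform(0.15, 0.85, size=n)
    coords = [_event_coords(rng, t, int(a)) for t, a in zip(types, anchors)]
    gene_ids = [f"ENSG{i:08d}" for i in rng.integers(0, max(2, n // 3), size=n)]
    symbols = [g.replace("ENSG", "SYN") for g in gene_ids]

    tables: dict[str, pd.DataFrame] = {}
    truth: dict[str, pd.Series] = {}
    for label in spec.comparisons:
        planted = dict(spec.planted_significant.get(label, {}))
        psi1 = base_psi.copy()
        psi2 = base_psi.copy()
        for idx, dpsi in planted.items():
            # shift group 2 down (or up when hitting the floor) by dpsi
            if psi1[idx] - dpsi >= 0.02:
                psi2[idx] = psi1[idx] - dpsi
            else:
                psi2[idx] = min(psi1[idx] + dpsi, 0.98)
        rows = []
        for i in range(n):
            d1 = rng.poisson(spec.mean_junction_depth, spec.reps_per_side) + 1
            d2 = rng.poisson(spec.mean_junction_depth, spec.reps_per_side) + 1
            inc1 = rng.binomial(d1, psi1[i])
            inc2 = rng.binomial(d2, psi2[i])
            skip1 = d1 - inc1
            skip2 = d2 - inc2
            # PSIs are serialised to 3 decimals; compute them (and the
            # difference below) from the rounded values so the record
            # invariant ILD == mean(psi1) - mean(psi2) survives a round-trip
            p1 = (inc1 / d1).round(3)
            p2 = (inc2 / d2).round(3)
            # two-proportion z-test on summed junction counts
            x = np.array([inc1.sum(), inc2.sum()])
            ntot = np.array([d1.sum(), d2.sum()])
            pool = x.sum() / ntot.sum()
            se = np.sqrt(pool * (1 - pool) * (1 / ntot[0] + 1 / ntot[1]))
            zstat = (x[0] / ntot[0] - x[1] / ntot[1]) / se if se > 0 else 0.0
            pval = float(2 * stats.norm.sf(abs(zstat)))
            rows.append(
                {
                    "event_type": types[i],
                    "gene_id": gene_ids[i],
                    "gene_symbol": symbols[i],
                    "chrom": chroms[i],
                    "strand": strands[i],
                    "coords": coords[i],
                    "inc_counts_g1": inc1.tolist(),
                    "skip_counts_g1": skip1.tolist(),
                    "inc_counts_g2": inc2.tolist(),
                    "skip_counts_g2": skip2.tolist(),
                    "psi_g1": p1.tolist(),
                    "psi_g2": p2.tolist(),
                    "pvalue": pval,
                }
            )
        df = pd.DataFrame(rows)
        df["inc_level_difference"] = [
            float(np.mean(r["psi_g1"]) - np.mean(r["psi_g2"])) for r in rows
        ]
        df["fdr"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df["key"] = [
            EventKey(r.event_type, r.chrom, r.strand, tuple(r.coords), r.gene_id)
            for r in df.itertuples(index=False)
        ]
        flags = np.zeros(n, dtype=bool)
        flags[list(planted)] = True
        tables[label] = df
        truth[label] = pd.Series(flags, index=df["key"], name="planted")
    return tables, truth
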