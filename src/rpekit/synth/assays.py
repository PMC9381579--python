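"""Small seeded assay fixtures with closed-form expected answers."""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUPS = ("control", "asymptomatic", "affected", "isogenic")


def generate_assay_fixtures(rng_seed: int = 0, n_per_group: int = 9) -> dict[str, pd.DataFrame]:
    """Tables for TER, phagocytosis, western, marker counting and qPCR.

    Each table carries the raw readings plus the context columns the
    corresponding quantification op needs; expected outputs are recomputable
    in closed form, which is what the test oracles do.
    """
    rng = np.random.default_rng(rng_seed)
    tables: dict[str, pd.DataFrame] = {}

    # TER: affected genotypes flat near blank, controls build resistance
    rows = []
    for g in GROUPS:
        level = 150.0 if g in ("control", "isogenic") else 5.0
        for i in range(n_per_group):
            blank = 100.0 + rng.normal(0, 2)
            raw = blank + level + rng.normal(0, 8)
            rows.append({"group": g, "replicate": i + 1, "raw_ohm": raw, "blank_ohm": blank, "area_cm2": 1.12})
    tables["ter"] = pd.DataFrame(rows)

    rows = []
    for g in GROUPS:
        internal = 3.0 if g in ("control", "isogenic") else 1.5  # twofold deficit
        bound = 2.0
        for i in range(n_per_group):
            dapi = rng.uniform(180, 260)
            quenched = internal * dapi * rng.lognormal(0, 0.08)
            total = quenched + bound * dapi * rng.lognormal(0, 0.08)
            rows.append({"group": g, "replicate": i + 1, "total_fitc": total, "quenched_fitc": quenched, "dapi": dapi})
    tables["phagocytosis"] = pd.DataFrame(rows)

    rows = []
    for g in GROUPS:
        level = 1.0 if g in ("control", "isogenic") else 0.2  # fivefold drop
        for i in range(max(n_per_group - 3, 3)):
            loading = rng.uniform(800, 1200)
            target = level * loading * rng.lognormal(0, 0.1)
            rows.append({"group": g, "replicate": i + 1, "target_band": target, "loading_band": loading})
    tables["western"] = pd.DataFrame(rows)

    rows = []
    for g in GROUPS:
        frac = 0.15 if g in ("control", "isogenic") else 0.05
        for i in range(n_per_group):
            n_dapi = int(rng.integers(250, 400))
            n_marker = int(rng.binomial(n_dapi, frac))
            area = float(rng.uniform(0.008, 0.012))
            rows.append({"group": g, "replicate": i + 1, "n_marker": n_marker, "n_dapi": n_dapi, "region_area_mm2": area})
    tables["counting"] = pd.DataFrame(rows)

    rows = []
    for g in GROUPS:
        shift = 0.0 if g == "control" else (2.0 if g == "affected" else 0.2)
        for i in range(3):
            ct_h = rng.uniform(9.0, 11.0)
            ct_t = ct_h + 8.0 + shift + rng.normal(0, 0.15)
            rows.append({"group": g, "replicate": i + 1, "gene": "TARGET1", "ct_target": ct_t, "ct_housekeeping": ct_h})
    tables["qpcr"] = pd.DataFrame(rows)
    return tables
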