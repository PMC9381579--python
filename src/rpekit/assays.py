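"""Closed-form quantification of the functional assays.

Each function maps raw instrument readings to the reported quantity:

- TER: transepithelial electrical resistance, blank-subtracted and scaled
  by membrane area, in ohm*cm^2.
- Phagocytosis: FITC-labelled photoreceptor outer segments fed to RPE
  cells; trypan-blue quenching removes the surface-bound signal, so
  quenched fluorescence measures internalised particles and the
  total-minus-quenched difference measures bound ones, each normalised to
  the DAPI nuclear signal.
- Western blots: band intensity relative to a loading control, expressed
  as fold over a reference group's mean ratio.
- Marker counts: percentage of immunoreactive cells among DAPI nuclei.
- ONL density: nuclei per unit cross-section area.
- qPCR: delta-Ct relative expression, fold = 2^-(dCt - dCt_ref).

All ops accept scalars or aligned array-likes and return numpy scalars or
arrays; `group_test` runs the omnibus comparison used throughout
(Kruskal-Wallis or one-way ANOVA with Dunn / Tukey post-hoc).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def ter_normalize(raw_ohm, blank_ohm, area_cm2):
    """Net transepithelial resistance in ohm*cm^2: (raw - blank) * area.

    Sub-blank readings yield negative values, returned as-is with a
    warning (they occur in practice and carry the sign information).
    """
    raw = np.asarray(raw_ohm, dtype=float)
    blank = np.asarray(blank_ohm, dtype=float)
    area = np.asarray(area_cm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("membrane area must be positive")
    if np.any(np.isnan(blank)):
        raise ValueError("blank reading is required")
    out = (raw - blank) * area
    if np.any(out < 0):
        logger.warning("ter_normalize: %d reading(s) below blank", int(np.sum(out < 0)))
    return out if out.ndim else float(out)


def phagocytosis_ratios(total_fitc, quenched_fitc, dapi, clamp: bool = True):
    """(internalized, bound) FITC/DAPI ratios.

    internalized = quenched / dapi; bound = (total - quenched) / dapi.
    Quenching noise can push total below quenched; the bound ratio is then
    clamped at 0 with a warning (disable with clamp=False).
    Pre-clamping, internalized + bound == total / dapi exactly.
    """
    total = np.asarray(total_fitc, dtype=float)
    quenched = np.asarray(quenched_fitc, dtype=float)
    dapi = np.asarray(dapi, dtype=float)
    if np.any(dapi <= 0):
        raise ValueError("DAPI signal must be positive")
    internalized = quenched / dapi
    bound = (total - quenched) / dapi
    if clamp and np.any(bound < 0):
        logger.warning("phagocytosis_ratios: clamping %d negative bound signal(s)", int(np.sum(bound < 0)))
        bound = np.maximum(bound, 0.0)
    if internalized.ndim == 0:
        return float(internalized), float(bound)
    return internalized, bound


def band_ratio_fold(target, loading, reference_group_mean_ratio):
    """Western-blot level relative to the loading control, and fold over reference.

    ratio = target / loading; fold = ratio / reference group mean ratio
    (arithmetic mean of the reference group's ratios).
    """
    target = np.asarray(target, dtype=float)
    loading = np.asarray(loading, dtype=float)
    ref = float(reference_group_mean_ratio)
    if np.any(loading <= 0):
        raise ValueError("loading-control intensity must be positive")
    if ref == 0:
        raise ValueError("reference group mean ratio is zero")
    ratio = target / loading
    fold = ratio / ref
    if ratio.ndim == 0:
        return float(ratio), float(fold)
    return ratio, fold


def marker_fraction(n_marker, n_dapi):
    """Marker-positive cells as a percentage of DAPI-positive nuclei."""
    nm = np.asarray(n_marker, dtype=float)
    nd = np.asarray(n_dapi, dtype=float)
    if np.any(nd <= 0):
        raise ValueError("DAPI count must be positive")
    if np.any(nm < 0) or np.any(nm > nd):
        raise ValueError("marker count must be within [0, DAPI count]")
    out = 100.0 * nm / nd
    return out if out.ndim else float(out)


def onl_density(n_dapi, region_area):
    """Nuclear density of the (presumptive) outer nuclear layer: count / area."""
    n = np.asarray(n_dapi, dtype=float)
    a = np.asarray(region_area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("region area must be positive")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    out = n / a
    return out if out.ndim else float(out)


def dct_fold(ct_target, ct_housekeeping, ref_delta_ct):
    """Relative expression by the delta-Ct method (base-2 amplification).

    dCt = Ct(target) - Ct(housekeeping); fold over the reference condition
    is 2^-(dCt - dCt_ref): one cycle earlier means twice the template.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_h = np.asarray(ct_housekeeping, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_h))):
        raise ValueError("Ct values must be finite")
    dct = ct_t - ct_h
    out = np.power(2.0, -(dct - float(ref_delta_ct)))
    return out if out.ndim else float(out)


def _dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with tie correction and Holm adjustment."""
    names = list(samples)
    values = np.concatenate([samples[g] for g in names])
    labels = np.concatenate([[g] * len(samples[g]) for g in names])
    ranks = stats.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            ni, nj = len(samples[gi]), len(samples[gj])
            se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": gi, "group2": gj, "z": z, "pvalue_raw": min(p, 1.0)})
    df = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(df["pvalue_raw"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * df["pvalue_raw"].iloc[idx])
        adj[idx] = min(running, 1.0)
    df["pvalue_adj"] = adj
    return df


def group_test(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    method: str = "kruskal",
    posthoc: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Omnibus comparison of assay values across groups.

    method="kruskal" (default) runs Kruskal-Wallis with Dunn's post-hoc;
    method="anova" runs one-way ANOVA with Tukey's HSD.  Post-hoc tests are
    reported regardless of the omnibus outcome.  Every group needs n >= 3.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    samples = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in samples.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n={len(v)} < 3")
    if method == "kruskal":
        stat, p = stats.kruskal(*samples.values())
        post = _dunn_posthoc(samples) if posthoc else None
    elif method == "anova":
        stat, p = stats.f_oneway(*samples.values())
        post = None
        if posthoc:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            vals = np.concatenate(list(samples.values()))
            labs = np.concatenate([[g] * len(v) for g, v in samples.items()])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tk = pairwise_tukeyhsd(vals, labs, alpha=alpha)
            post = pd.DataFrame(
                tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
            )
    else:
        raise ValueError("method must be 'kruskal' or 'anova'")
    return {
        "method": method,
        "statistic": float(stat),
        "pvalue": float(p),
        "significant": bool(p < alpha),
        "alpha": alpha,
        "group_summary": {
            g: {"n": int(len(v)), "mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            for g, v in samples.items()
        },
        "posthoc": post,
    }
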