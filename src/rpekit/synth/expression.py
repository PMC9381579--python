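"""Synthetic 3-replicate expression tables with planted group-specific genes.

Counts follow a negative-binomial model: per-gene baseline means are
log-normal, group effects are log2 offsets applied to planted gene sets,
and replicate counts are NB draws with a common dispersion (variance
mu + dispersion * mu^2).  Dispersion 0 is the noiseless limit (counts are
the rounded expected means), which makes closed-form checks exact.

Synthetic genes have unit length, so TPM reduces to counts rescaled to one
million per sample; gene length never enters the downstream filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

DEFAULT_GROUPS = ("control", "asymptomatic", "affected", "isogenic")


@dataclass(frozen=True)
class CountTableSpec:
    """Design of one synthetic count/TPM table.

    planted_sets maps each planted gene-index set to a per-group log2
    offset vector, e.g. (0, 0, +3, 0) for a gene up 8-fold in the affected
    group only.  Sets must be disjoint.
    """

    n_genes: int = 5000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    reps_per_group: int = 3
    baseline_log_mean: float = 5.5
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    planted_sets: tuple[tuple[tuple[int, ...], tuple[float, ...]], ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.reps_per_group < 1:
            raise ValueError("n_genes and reps_per_group must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        seen: set[int] = set()
        for idxs, offsets in self.planted_sets:
            if len(offsets) != len(self.groups):
                raise ValueError("offset vector length must match the number of groups")
            if not all(np.isfinite(offsets)):
                raise ValueError("offsets must be finite")
            if seen & set(idxs):
                raise ValueError("planted sets must be disjoint")
            seen |= set(idxs)
            if max(idxs, default=0) >= self.n_genes:
                raise ValueError("planted index out of range")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CountTableTruth:
    """Planted pattern per gene: offset vector index (-1 = background)."""

    pattern: pd.Series
    expected_mean: pd.DataFrame  # gene x group expected count means
    spec: CountTableSpec = field(repr=False, default=None)


def generate_count_table(
    spec: CountTableSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, CountTableTruth]:
    """Generate (counts, TPM, truth); columns are `<group>_<rep>` sample ids."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    samples = [f"{g}_{r+1}" for g in spec.groups for r in range(spec.reps_per_group)]
    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)

    offsets = np.zeros((spec.n_genes, len(spec.groups)))
    pattern = np.full(spec.n_genes, -1, dtype=int)
    for k, (idxs, off) in enumerate(spec.planted_sets):
        offsets[list(idxs)] = np.asarray(off)
        pattern[list(idxs)] = k

    mu = base[:, None] * np.power(2.0, offsets)  # gene x group expected means
    counts = np.empty((spec.n_genes, len(samples)))
    for j, g in enumerate(spec.groups):
        m = mu[:, j]
        for r in range(spec.reps_per_group):
            col = j * spec.reps_per_group + r
            if spec.dispersion == 0:
                counts[:, col] = np.round(m)
            else:
                n_param = 1.0 / spec.dispersion
                p_param = n_param / (n_param + m)
                counts[:, col] = rng.negative_binomial(n_param, p_param)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    # unit-length genes: TPM is counts scaled to 1e6 per sample
    tpm_df = counts_df / counts_df.sum(axis=0) * 1e6
    truth = CountTableTruth(
        pattern=pd.Series(pattern, index=genes, name="pattern"),
        expected_mean=pd.DataFrame(mu, index=genes, columns=list(spec.groups)),
        spec=spec,
    )
    return counts_df, tpm_df, truth


def sample_groups(spec: CountTableSpec) -> pd.Series:
    """Sample id -> group label mapping matching generate_count_table columns."""
    samples = [f"{g}_{r+1}" for g in spec.groups for r in range(spec.reps_per_group)]
    labels = [g for g in spec.groups for _ in range(spec.reps_per_group)]
    return pd.Series(labels, index=samples, name="group")


def _moderated_pvalues(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Empirical-Bayes moderated t-test per row (limma-style).

    Per-gene pooled variances are squeezed toward a common prior fitted by
    moment-matching the log-variance distribution (trigamma inversion);
    the moderated t has df = residual df + prior df.  With triplicate
    groups an unmoderated t caps out near p ~ 1e-3, far from what
    genome-wide FDR control needs; sharing variance information across
    genes is how real small-n RNA-seq testing gets its power.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    df_resid = n1 + n2 - 2
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e_z = z.mean() - special.digamma(df_resid / 2) + np.log(df_resid / 2)
    var_z = max(z.var(ddof=1) - special.polygamma(1, df_resid / 2), 0.0)
    if var_z <= 1e-8:
        df_prior = np.inf
        s2_prior = np.exp(e_z)
    else:
        # invert trigamma(d0/2) = var_z for the prior df
        d = 2.0 * (1.0 + 1.0 / var_z)  # initial guess from 1/x asymptote
        for _ in range(50):
            tri = special.polygamma(1, d / 2)
            step = tri * (1 - tri / var_z) / special.polygamma(2, d / 2) * 2
            d = max(d + step, 0.1)
            if abs(tri - var_z) < 1e-10 * var_z:
                break
        df_prior = d
        s2_prior = np.exp(e_z - special.digamma(d / 2) + np.log(d / 2))
    if np.isinf(df_prior):
        s2_mod = np.full_like(s2, s2_prior)
        df_total = 1e6
    else:
        s2_mod = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
        df_total = df_prior + df_resid
    t = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(np.abs(t), df_total)


def make_de_stats(
    tpm: pd.DataFrame,
    groups: pd.Series,
    contrasts: list[tuple[str, str]],
) -> pd.DataFrame:
    """Stand-in DE statistics for synthetic tables.

    Per contrast (g1 vs g2): empirical log2FC of group-mean TPM (0.5
    pseudo-count), a moderated t-test on log2(TPM+1) (variance squeezed
    across genes, emulating the information sharing of an edgeR/limma-style
    upstream fit), and BH-adjusted FDR within the contrast.  This is a
    generator stand-in for the statistics a DE tool supplies, not a DE
    method of its own.
    """
    log = np.log2(tpm + 1.0)
    rows = []
    for g1, g2 in contrasts:
        s1 = groups.index[groups == g1]
        s2 = groups.index[groups == g2]
        if len(s1) == 0 or len(s2) == 0:
            raise ValueError(f"contrast {g1} vs {g2}: unknown group")
        m1 = tpm[s1].mean(axis=1)
        m2 = tpm[s2].mean(axis=1)
        lfc = np.log2((m1 + 0.5) / (m2 + 0.5))
        if len(s1) > 1 and len(s2) > 1:
            p = _moderated_pvalues(log[s1].to_numpy(), log[s2].to_numpy())
            p = np.where(np.isfinite(p), p, 1.0)
        else:
            p = np.ones(len(tpm))
        fdr = multipletests(p, method="fdr_bh")[1]
        rows.append(
            pd.DataFrame(
                {
                    "contrast": f"{g1}_vs_{g2}",
                    "gene_id": tpm.index,
                    "log2fc": lfc.to_numpy(),
                    "pval": p,
                    "fdr": fdr,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
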