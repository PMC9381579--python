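"""Mutation-specific differential-expression selection.

Takes per-gene TPM and per-contrast DE statistics (computed upstream by an
edgeR-style tool) and reproduces the downstream selection layer used for
case/carrier/control iPSC designs:

- expression floor (TPM >= 5 in at least one sample, or one group mean),
- DEG filter (|log2FC| >= 1 and FDR or p below alpha),
- z-scoring of group-mean log2(TPM+1) profiles,
- Ward hierarchical clustering of z-profiles into K clusters,
- selection of the clusters whose centroid separates the affected group
  from every control-like group by a margin delta.

The selected gene list (union over selected clusters) is the
"mutation-specific" DEG set: genes whose expression moves in the affected
samples but stays flat in both the unaffected control and the asymptomatic
carrier / isogenic control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """DEG filter thresholds.

    fc_min is the fold-change threshold on the natural scale (2 means
    |log2FC| >= 1, boundary inclusive); alpha applies to the column named
    by alpha_column (strict <); tpm_min is the expression floor, inclusive.
    tpm_mode chooses whether the floor applies to the per-sample maximum
    ("sample") or the per-group-mean maximum ("group").
    """

    fc_min: float = 2.0
    alpha: float = 0.05
    alpha_column: str = "fdr"  # or "pval"
    tpm_min: float = 5.0
    tpm_mode: str = "sample"  # or "group"

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha_column not in ("fdr", "pval"):
            raise ValueError("alpha_column must be 'fdr' or 'pval'")
        if self.tpm_min < 0:
            raise ValueError("tpm_min must be >= 0")
        if self.tpm_mode not in ("sample", "group"):
            raise ValueError("tpm_mode must be 'sample' or 'group'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClusterResult:
    K: int
    assignments: pd.Series  # gene id -> cluster id (1..K)
    selected: list[int] = field(default_factory=list)
    selected_genes: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _group_means(tpm: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean of each gene row; columns ordered as first appearance."""
    order = list(dict.fromkeys(groups))
    return pd.DataFrame(
        {g: tpm.loc[:, groups.index[groups == g]].mean(axis=1) for g in order}
    )


def tpm_filter(
    tpm: pd.DataFrame,
    groups: pd.Series | None = None,
    tpm_min: float = 5.0,
    mode: str = "sample",
) -> set[str]:
    """Genes whose expression clears the TPM floor.

    mode="sample": max over samples >= tpm_min (the RPE-stage reading);
    mode="group": max over group means >= tpm_min (the organoid reading,
    which needs `groups`).
    """
    if mode == "group":
        if groups is None:
            raise ValueError("group-mode TPM filter needs a group assignment")
        values = _group_means(tpm, groups).max(axis=1)
    else:
        values = tpm.max(axis=1)
    kept = set(tpm.index[values >= tpm_min])
    if not kept:
        logger.warning("tpm_filter: no gene passed the TPM >= %g floor", tpm_min)
    return kept


def deg_filter(
    stats: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    expressed: set[str] | None = None,
) -> dict[str, set[str]]:
    """Per-contrast DEG sets plus their union under key "union".

    `stats` needs columns: contrast, gene_id, log2fc, pval, fdr.
    A gene is a DEG for a contrast when |log2FC| >= log2(fc_min), its
    alpha-column value is < alpha, and it passed the expression floor.
    """
    required = {"contrast", "gene_id", "log2fc", config.alpha_column}
    for contrast, sub in stats.groupby("contrast"):
        missing = required - set(sub.columns)
        if missing:
            raise ValueError(f"contrast {contrast!r} is missing columns {sorted(missing)}")
    lfc_min = np.log2(config.fc_min)
    out: dict[str, set[str]] = {}
    union: set[str] = set()
    for contrast, sub in stats.groupby("contrast", sort=False):
        keep = (sub["log2fc"].abs() >= lfc_min) & (sub[config.alpha_column] < config.alpha)
        genes = set(sub.loc[keep, "gene_id"])
        if expressed is not None:
            genes &= expressed
        out[str(contrast)] = genes
        union |= genes
    out["union"] = union
    return out


def zscore_profiles(
    tpm: pd.DataFrame, groups: pd.Series, genes: list[str] | set[str] | None = None
) -> pd.DataFrame:
    """Per-gene z-profile of group-mean log2(TPM+1).

    Group means are standardised across groups per gene (population SD),
    so every profile has mean 0 and SD 1 over the groups.  Genes constant
    across groups carry no pattern and are dropped with a log message.
    """
    if genes is not None:
        genes = [g for g in tpm.index if g in set(genes)]
        tpm = tpm.loc[genes]
    means = _group_means(np.log2(tpm + 1.0), groups)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    constant = sd <= 1e-12
    if constant.any():
        logger.info("zscore_profiles: dropping %d constant gene(s)", int(constant.sum()))
    z = means.loc[~constant].sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return z


def cluster_genes(z: pd.DataFrame, K: int = 15) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of z-profiles, cut at K.

    Deterministic for a fixed input; the partition is invariant (as a set
    of gene sets) under permutation of the input rows.  K greater than the
    number of genes degrades to singletons.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    n = len(z)
    if n == 0:
        raise ValueError("no genes to cluster")
    if n < K:
        logger.warning("cluster_genes: only %d genes for K=%d; using singletons", n, K)
        K = n
    if n == 1:
        labels = np.array([1])
    else:
        # sort rows for order-invariance, cluster, then map back
        order = np.argsort(z.index.to_numpy())
        zs = z.iloc[order]
        link = linkage(zs.to_numpy(), method="ward", metric="euclidean")
        lab_sorted = fcluster(link, t=K, criterion="maxclust")
        labels = np.empty(n, dtype=int)
        labels[order] = lab_sorted
    return ClusterResult(
        K=int(labels.max()),
        assignments=pd.Series(labels, index=z.index, name="cluster"),
        params={"linkage": "ward", "metric": "euclidean", "K_requested": K},
    )


def select_clusters(
    result: ClusterResult,
    z: pd.DataFrame,
    affected_group: str,
    control_groups: list[str],
    delta: float = 1.0,
) -> ClusterResult:
    """Mark clusters whose centroid is affected-specific.

    A cluster is selected iff its centroid z-profile satisfies
    |z(affected) - z(g)| >= delta for every control-like group g: the
    pattern is present in the affected group and absent everywhere else.
    """
    if affected_group not in z.columns:
        raise ValueError(f"affected group {affected_group!r} not in z-profile columns")
    for g in control_groups:
        if g not in z.columns:
            raise ValueError(f"control group {g!r} not in z-profile columns")
    selected: list[int] = []
    for cid in sorted(result.assignments.unique()):
        members = result.assignments.index[result.assignments == cid]
        centroid = z.loc[members].mean(axis=0)
        if all(abs(centroid[affected_group] - centroid[g]) >= delta for g in control_groups):
            selected.append(int(cid))
    genes = list(result.assignments.index[result.assignments.isin(selected)])
    return ClusterResult(
        K=result.K,
        assignments=result.assignments,
        selected=selected,
        selected_genes=genes,
        params={**result.params, "affected": affected_group, "controls": list(control_groups), "delta": delta},
    )


def mutation_specific_genes(
    tpm: pd.DataFrame,
    groups: pd.Series,
    stats: pd.DataFrame,
    affected_group: str,
    control_groups: list[str],
    config: FilterConfig = FilterConfig(),
    K: int = 15,
    delta: float = 1.0,
) -> dict:
    """Full selection pipeline: TPM floor -> DEG filter -> z -> cluster -> select.

    Returns a dict with the per-contrast DEG sets, the cluster result and
    the final mutation-specific gene list.  With no DEGs at all the result
    is empty rather than an error (a real null contrast is a valid outcome).
    """
    expressed = tpm_filter(tpm, groups, config.tpm_min, config.tpm_mode)
    degs = deg_filter(stats, config, expressed)
    union = sorted(degs["union"])
    if len(union) == 0:
        return {"degs": degs, "clusters": None, "selected_genes": []}
    z = zscore_profiles(tpm, groups, union)
    if len(z) == 0:
        return {"degs": degs, "clusters": None, "selected_genes": []}
    clusters = cluster_genes(z, K=K)
    clusters = select_clusters(clusters, z, affected_group, control_groups, delta=delta)
    return {"degs": degs, "clusters": clusters, "selected_genes": clusters.selected_genes}
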