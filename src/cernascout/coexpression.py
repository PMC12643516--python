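"""Weighted coexpression network over the mixed lncRNA + mRNA matrix.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the
soft-threshold power beta chosen for approximate scale-free topology.
Topological overlap (TOM) similarity feeds average-linkage clustering;
modules come from a static cut of the dendrogram, eigengenes are first
principal components of the standardized member submatrices, and the
hub lncRNA of a module is its lncRNA of highest intramodular
connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "remove_outlier_samples",
    "correlation_adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "intramodular_connectivity",
    "select_hub_lncrna",
    "ModulePartition",
]

# deep-split -> fraction of the merge-height range at which the tree is cut
# (deeper split = lower cut = more aggressive splitting); the fractions are
# calibrated so that a medium split (2) recovers latent-factor modules whose
# 1-TOM dissimilarities are compressed near 1, while strong block structure
# is unaffected by the exact value
DEEP_SPLIT_Q = {0: 0.97, 1: 0.96, 2: 0.95, 3: 0.93, 4: 0.90}


@dataclass
class ModulePartition:
    """Module labels (0 = unassigned), eigengenes and connectivity."""

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    k_within: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    hubs: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels.unique()) - {0})

    def members(self, module_id: int) -> pd.Index:
        return self.labels.index[self.labels == module_id]


def remove_outlier_samples(
    dataset: ExpressionDataset, cut_height_frac: float = 0.75
) -> tuple[ExpressionDataset, list[str]]:
    """Drop samples outside the main sample cluster.

    Samples are clustered by average linkage on Euclidean distance; the
    tree is cut at ``cut_height_frac`` times the maximum merge height
    and everything outside the largest cluster is removed.  If the
    would-be main cluster holds less than 75% of the samples the tree
    has no dominant cluster (e.g. it split on biology rather than on
    outliers) and nothing is removed.
    """
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    x = dataset.values.to_numpy(dtype=float).T
    link = hierarchy.linkage(x, method="average", metric="euclidean")
    max_height = link[:, 2].max()
    clusters = hierarchy.fcluster(link, t=cut_height_frac * max_height, criterion="distance")
    sizes = pd.Series(clusters).value_counts()
    main = sizes.idxmax()
    keep = clusters == main
    if keep.sum() < 0.75 * dataset.n_samples:
        logger.warning(
            "cohort %s: no dominant sample cluster at cut %.2f x max height; "
            "skipping outlier removal", dataset.cohort_id, cut_height_frac,
        )
        keep = np.ones(dataset.n_samples, dtype=bool)
    if keep.sum() == 0:
        raise ValueError("all samples removed as outliers")
    removed = [s for s, k in zip(dataset.sample_ids, keep) if not k]
    if removed:
        trimmed = ExpressionDataset(
            values=dataset.values.loc[:, keep],
            biotype=dataset.biotype.copy(),
            group=dataset.group[keep],
            cohort_id=dataset.cohort_id,
            is_log=dataset.is_log,
        )
    else:
        trimmed = dataset
    return trimmed, removed


def correlation_adjacency(dataset: ExpressionDataset, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |Pearson cor|^beta with zero diagonal."""
    x = dataset.values
    if x.isna().any().any():
        cor = x.T.corr(method="pearson")  # pairwise-complete
        cor = cor.to_numpy()
    else:
        cor = np.corrcoef(x.to_numpy(dtype=float))
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=x.index, columns=x.index)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-distribution regression.

    Connectivity is histogrammed into ``n_bins`` equal-width bins on
    log10 scale (empty bins dropped); log10 frequency is regressed on
    log10 mean connectivity per bin.  Returns -sign(slope) * R^2, or
    NaN when fewer than two usable bins remain.
    """
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return np.nan
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    edges[-1] += 1e-9
    idx = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 2:
        return np.nan
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return -np.sign(slope) * r2


def pick_soft_threshold(
    dataset: ExpressionDataset,
    betas: list[float] | None = None,
    r2_goal: float = 0.80,
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power for scale-free topology.

    Returns the smallest candidate beta whose signed scale-free R^2
    reaches ``r2_goal``; if none does, the beta with the maximum signed
    R^2 is returned with a warning.  The fit table reports signed R^2
    and mean connectivity per candidate.
    """
    if dataset.n_features < 10:
        raise ValueError("need at least 10 features to fit scale-free topology")
    if betas is None:
        betas = [1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16]
    rows = []
    for beta in betas:
        adj = correlation_adjacency(dataset, beta).to_numpy()
        k = adj.sum(axis=1)
        rows.append(
            {"beta": beta, "signed_r2": _scale_free_fit(k), "mean_k": float(k.mean())}
        )
    fit_table = pd.DataFrame(rows)
    good = fit_table[fit_table["signed_r2"] >= r2_goal]
    if len(good):
        beta = float(good.iloc[0]["beta"])
    else:
        usable = fit_table.dropna(subset=["signed_r2"])
        if not len(usable):
            raise ValueError("scale-free fit undefined for every candidate beta")
        beta = float(usable.loc[usable["signed_r2"].idxmax(), "beta"])
        logger.warning(
            "no candidate beta reached R^2 >= %.2f; using beta=%g at the maximum",
            r2_goal, beta,
        )
    return beta, fit_table


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, and TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.nan_to_num(tom, nan=0.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 30, deep_split: int = 2
) -> ModulePartition:
    """Cut the 1-TOM average-linkage dendrogram into modules.

    The static cut height is placed at the ``DEEP_SPLIT_Q[deep_split]``
    fraction of the merge-height range (between the first and the last
    merge), so that the cut adapts to how compressed the dissimilarity
    scale is.  Clusters smaller than ``min_module_size`` fall into
    module 0; surviving modules are numbered by decreasing size.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if deep_split not in DEEP_SPLIT_Q:
        raise ValueError(f"deep_split must be one of {sorted(DEEP_SPLIT_Q)}")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    heights = link[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    cut = h_min + DEEP_SPLIT_Q[deep_split] * (h_max - h_min)
    clusters = hierarchy.fcluster(link, t=cut, criterion="distance")

    sizes = pd.Series(clusters).value_counts()
    big = sizes[sizes >= min_module_size]
    if big.empty:
        logger.warning("no cluster reached min_module_size=%d; all unassigned", min_module_size)
    order = big.sort_values(ascending=False).index
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series(
        [relabel.get(c, 0) for c in clusters], index=tom.index, name="module"
    )
    return ModulePartition(labels=labels)


def module_eigengene(dataset: ExpressionDataset, partition: ModulePartition) -> pd.DataFrame:
    """First principal component per module (samples x modules).

    Member profiles are z-scored per feature; the eigengene is scaled
    to unit variance and sign-oriented so its mean correlation with the
    members is non-negative.  A single-member module's eigengene is the
    member's z-score.
    """
    eigengenes = {}
    x = dataset.values
    for module_id in partition.module_ids:
        members = partition.members(module_id)
        sub = x.loc[members].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd <= 0, 1.0, sd)
        z = (sub - mu) / sd
        if z.shape[0] == 1:
            me = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
        sd_me = me.std(ddof=1)
        if sd_me > 0:
            me = (me - me.mean()) / sd_me
        if z.shape[0] > 1:
            mean_cor = np.mean([np.corrcoef(me, row)[0, 1] for row in z])
            if mean_cor < 0:
                me = -me
        eigengenes[f"ME{module_id}"] = me
    result = pd.DataFrame(eigengenes, index=x.columns)
    partition.eigengenes = result
    return result


def intramodular_connectivity(
    adjacency: pd.DataFrame, partition: ModulePartition
) -> pd.Series:
    """k_within(i) = sum of adjacency to same-module members (self excluded)."""
    a = adjacency.to_numpy(dtype=float)
    labels = partition.labels.reindex(adjacency.index).to_numpy()
    k_within = np.zeros(len(labels))
    for module_id in np.unique(labels):
        mask = labels == module_id
        k_within[mask] = a[np.ix_(mask, mask)].sum(axis=1)
    result = pd.Series(k_within, index=adjacency.index, name="k_within")
    partition.k_within = result
    return result


def select_hub_lncrna(
    partition: ModulePartition,
    k_within: pd.Series,
    node_biotype: pd.Series,
    meta_table: pd.DataFrame | None = None,
    adjacency: pd.DataFrame | None = None,
    edge_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Pick each module's hub lncRNA by maximal intramodular connectivity.

    Ties break by (1) more adjacency edges at or above ``edge_cutoff``,
    then (2) smaller meta ``p_comb_adj``.  Modules without a lncRNA are
    reported hub-less (NaN row).  Returns one row per module with the
    hub's connectivity, edge count, and meta statistics when available.
    """
    columns = ["module", "hub", "k_within", "edges_above_cutoff", "p_comb_adj", "T_comb"]
    rows = []
    for module_id in partition.module_ids:
        members = partition.members(module_id)
        lncs = [m for m in members if node_biotype.get(m) == "lncRNA"]
        if not lncs:
            rows.append({"module": module_id, "hub": None, "k_within": np.nan,
                         "edges_above_cutoff": 0, "p_comb_adj": np.nan,
                         "T_comb": np.nan})
            continue

        def edge_count(node: str) -> int:
            if adjacency is None:
                return 0
            return int((adjacency.loc[node] >= edge_cutoff).sum())

        def meta_p(node: str) -> float:
            if meta_table is None or node not in meta_table.index:
                return np.inf
            return float(meta_table.loc[node, "p_comb_adj"])

        best = sorted(
            lncs,
            key=lambda n: (-k_within.get(n, 0.0), -edge_count(n), meta_p(n), n),
        )[0]
        rows.append({
            "module": module_id,
            "hub": best,
            "k_within": float(k_within.get(best, np.nan)),
            "edges_above_cutoff": edge_count(best),
            "p_comb_adj": (
                float(meta_table.loc[best, "p_comb_adj"])
                if meta_table is not None and best in meta_table.index else np.nan
            ),
            "T_comb": (
                float(meta_table.loc[best, "T_comb"])
                if meta_table is not None and best in meta_table.index else np.nan
            ),
        })
    hubs = pd.DataFrame(rows, columns=columns)
    partition.hubs = hubs
    return hubs
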