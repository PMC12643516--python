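"""Over-representation and gene-set enrichment statistics.

ORA is the hypergeometric upper tail over a fixed universe with
Benjamini-Hochberg (and optionally Bonferroni) correction.  GSEA is the
classic weighted running-sum statistic; its null is generated by
gene-label permutation (dataset-free), so nominal p-values carry the
+1 small-sample correction and can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GeneSetCollection

__all__ = [
    "bh_adjust",
    "bonferroni_adjust",
    "hypergeom_ora",
    "ora_table",
    "gsea",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone non-decreasing in p-rank and always >= the raw p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_adjust(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# over-representation analysis


def hypergeom_ora(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` hits from a gene set of size ``K`` in a list of ``n`` drawn
    from a universe of ``N``.
    """
    if N <= 0:
        raise ValueError("universe is empty")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_table(
    hits: list[str] | set[str],
    collection: GeneSetCollection,
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """ORA over every set in ``collection``.

    Hits are intersected with the universe; each gene set is likewise
    restricted to the universe before testing.  Returns a table with
    overlap counts, the hypergeometric p, BH- and Bonferroni-adjusted
    p, and the enrichment ratio (k/n)/(K/N).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    hits = set(hits) & universe
    n, N = len(hits), len(universe)
    rows = []
    for name, (desc, members) in collection:
        member_set = set(members) & universe
        K = len(member_set)
        if K == 0:
            continue
        k = len(hits & member_set)
        p = hypergeom_ora(k, K, n, N)
        ratio = (k / n) / (K / N) if n > 0 else np.nan
        rows.append({"set": name, "description": desc, "k": k, "K": K,
                     "n": n, "N": N, "p": p, "enrichment_ratio": ratio})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["p_bonferroni"] = bonferroni_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# gene-set enrichment analysis


@dataclass
class GseaResult:
    table: pd.DataFrame
    running_sums: dict[str, np.ndarray] = field(default_factory=dict)


def _enrichment_score(
    in_set: np.ndarray, weights: np.ndarray, miss_penalty: float
) -> float:
    """Signed max deviation of the running sum for one hit indicator."""
    steps = np.where(in_set, weights, -miss_penalty)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked_stats: pd.Series,
    collection: GeneSetCollection,
    weight_exponent: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
    keep_running_sums: bool = False,
) -> GseaResult:
    """Weighted running-sum gene-set enrichment with a permutation null.

    ``ranked_stats`` maps feature -> score and is sorted to descending
    score internally.  Hit increments are |score|^w normalized over the
    set; misses decrement 1/(N-K).  The null distribution comes from
    ``nperm`` gene-label permutations with a fixed seed; NES divides ES
    by the mean |null ES| of matching sign, and the nominal p is the
    two-sided permutation tail (|null ES| >= |ES|) with the +1
    correction, so it can never be exactly zero.  Sets that cover the
    whole ranked list (no misses) are reported as NA.
    """
    if nperm < 100:
        raise ValueError("nperm must be at least 100")
    ranked = ranked_stats.sort_values(ascending=False, kind="stable")
    scores = ranked.to_numpy(dtype=float)
    genes = ranked.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    weights_all = np.abs(scores) ** weight_exponent
    rng = np.random.default_rng(seed)

    rows = []
    running_sums: dict[str, np.ndarray] = {}
    for name, (_, members) in collection:
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        K = idx.size
        if K == 0 or K == N:
            rows.append({"set": name, "K": K, "ES": np.nan, "NES": np.nan,
                         "p": np.nan})
            continue
        in_set = np.zeros(N, dtype=bool)
        in_set[idx] = True
        set_weights = weights_all / weights_all[in_set].sum()
        miss = 1.0 / (N - K)
        es = _enrichment_score(in_set, set_weights, miss)
        if keep_running_sums:
            steps = np.where(in_set, set_weights, -miss)
            running_sums[name] = np.cumsum(steps)

        null_es = np.empty(nperm)
        for b in range(nperm):
            perm = np.zeros(N, dtype=bool)
            perm[rng.choice(N, size=K, replace=False)] = True
            w = weights_all / weights_all[perm].sum()
            null_es[b] = _enrichment_score(perm, w, miss)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        denom = np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        extreme = int(np.sum(np.abs(null_es) >= abs(es)))
        p = (1 + extreme) / (nperm + 1)
        rows.append({"set": name, "K": K, "ES": es, "NES": nes, "p": p})

    table = pd.DataFrame(rows)
    if len(table):
        valid = table["p"].notna()
        table["p_adj"] = np.nan
        if valid.any():
            table.loc[valid, "p_adj"] = bh_adjust(table.loc[valid, "p"].to_numpy())
    return GseaResult(table=table, running_sums=running_sums)
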