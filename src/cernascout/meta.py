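"""Per-cohort differential expression and cross-cohort meta-analysis.

Each cohort is normalized (log2 if raw, then quantile normalization),
optionally batch-adjusted with an empirical-Bayes location/scale model,
and tested feature-by-feature with the empirical-Bayes moderated
two-sample t-statistic.  Cohorts are then combined per feature by

* the combined T statistic  T_comb = sum of per-cohort moderated t, and
* Fisher's method           X2 = -2 * sum(ln p_i) ~ chi2 with 2k df,

with Benjamini-Hochberg adjustment of the combined p across features.
Which per-cohort p enters Fisher's method (raw or BH-adjusted) is a
per-panel choice: mRNA panels combine raw p, miRNA panels combine
adjusted p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special

from .datasets import ExpressionDataset, FormatError
from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize",
    "combat_adjust",
    "moderated_t",
    "fisher_combine",
    "combined_t",
    "run_meta",
    "preprocess",
    "collapse_probes",
]

P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# normalization


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Force every sample (column) onto the same empirical distribution.

    The reference distribution is the vector of row-wise means of the
    column-sorted values; ties within a column receive the average of
    the reference values at the tied ranks.  Idempotent.
    """
    x = dataset.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise FormatError("quantile normalization cannot handle masked values")
    if x.shape[1] < 2:
        return dataset.with_values(dataset.values.copy())
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    ranks_grid = np.arange(1, x.shape[0] + 1, dtype=float)
    for col in range(x.shape[1]):
        ranks = stats.rankdata(x[:, col], method="average")
        out[:, col] = np.interp(ranks, ranks_grid, reference)
    values = pd.DataFrame(out, index=dataset.values.index, columns=dataset.values.columns)
    return dataset.with_values(values)


def preprocess(dataset: ExpressionDataset) -> ExpressionDataset:
    """log2(x+1) for raw-intensity cohorts, then quantile normalization."""
    if not dataset.is_log:
        values = np.log2(dataset.values.clip(lower=0) + 1.0)
        dataset = dataset.with_values(values, is_log=True)
    return quantile_normalize(dataset)


def collapse_probes(dataset: ExpressionDataset, probe_to_gene: pd.Series) -> ExpressionDataset:
    """Collapse probes mapping to the same gene.

    Keeps, per gene, the probe with maximum mean expression (a common
    microarray convention).
    """
    means = dataset.values.mean(axis=1)
    keep: dict[str, str] = {}
    for probe in dataset.values.index:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in keep or means[probe] > means[keep[gene]]:
            keep[gene] = probe
    probes = list(keep.values())
    values = dataset.values.loc[probes]
    values.index = list(keep.keys())
    biotype = dataset.biotype.loc[probes]
    biotype.index = list(keep.keys())
    return ExpressionDataset(
        values=values, biotype=biotype, group=dataset.group.copy(),
        cohort_id=dataset.cohort_id, is_log=dataset.is_log,
    )


# ---------------------------------------------------------------------------
# ComBat-style batch adjustment


def combat_adjust(dataset: ExpressionDataset, batch: pd.Series) -> ExpressionDataset:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Features are standardized while preserving the case/control effect
    (the group term is part of the design and re-fit afterwards, not
    removed); per-batch additive effects get a normal prior and
    multiplicative effects an inverse-gamma prior, both shrunk toward
    their across-feature moments before back-transformation.
    """
    batch = batch.reindex(dataset.values.columns)
    if batch.isna().any():
        missing = batch.index[batch.isna()][0]
        raise FormatError(f"sample {missing!r} has no batch label")
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return dataset.with_values(dataset.values.copy())
    for level in levels:
        n_b = int((batch == level).sum())
        if n_b < 2:
            raise FormatError(f"batch {level!r} has fewer than 2 samples")
        groups_in_batch = dataset.group[batch == level].unique()
        if len(groups_in_batch) < 2:
            raise FormatError("batch confounded with condition")

    x = dataset.values.to_numpy(dtype=float)
    case = dataset.case_mask().astype(float)
    n_features, n_samples = x.shape

    # design: intercept + group, plus batch indicators (reference-free)
    batch_codes = pd.Categorical(batch, categories=levels).codes
    B = np.zeros((n_samples, len(levels)))
    B[np.arange(n_samples), batch_codes] = 1.0
    design = np.column_stack([B, case])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    beta = beta.T  # features x (len(levels) + 1)
    batch_props = B.sum(axis=0) / n_samples
    grand_mean = beta[:, : len(levels)] @ batch_props
    group_effect = beta[:, -1]

    stand_mean = (
        grand_mean[:, None] + group_effect[:, None] * case[None, :]
    )
    resid = x - stand_mean - (beta[:, : len(levels)] - grand_mean[:, None]) @ B.T
    pooled_var = (resid**2).mean(axis=1)
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)
    z = (x - stand_mean) / np.sqrt(pooled_var)[:, None]

    adjusted = np.empty_like(z)
    for b_idx, level in enumerate(levels):
        cols = batch_codes == b_idx
        n_b = int(cols.sum())
        gamma_hat = z[:, cols].mean(axis=1)
        delta_hat = z[:, cols].var(axis=1, ddof=1)
        delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)

        # hyperpriors by method of moments (as in the parametric model)
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1) if n_features > 1 else 0.0
        d_bar, s2 = delta_hat.mean(), delta_hat.var(ddof=1) if n_features > 1 else 0.0
        if s2 > 0:
            a_prior = (2 * s2 + d_bar**2) / s2
            b_prior = (d_bar * s2 + d_bar**3) / s2
        else:
            a_prior, b_prior = np.inf, np.nan

        # one-step EB shrinkage (non-iterative variant of the usual fit)
        if tau2 > 0:
            gamma_star = (n_b * tau2 * gamma_hat + delta_hat * gamma_bar) / (
                n_b * tau2 + delta_hat
            )
        else:
            gamma_star = np.full(n_features, gamma_bar)
        if np.isfinite(a_prior):
            sse = ((z[:, cols] - gamma_star[:, None]) ** 2).sum(axis=1)
            delta_star = (b_prior + 0.5 * sse) / (n_b / 2 + a_prior - 1)
            delta_star = np.where(delta_star <= 0, delta_hat, delta_star)
        else:
            delta_star = delta_hat
        adjusted[:, cols] = (z[:, cols] - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * np.sqrt(pooled_var)[:, None] + stand_mean
    values = pd.DataFrame(out, index=dataset.values.index, columns=dataset.values.columns)
    return dataset.with_values(values)


# ---------------------------------------------------------------------------
# moderated t


@dataclass
class DEResult:
    """Per-feature differential expression for one cohort."""

    table: pd.DataFrame  # logFC, t_mod, df, p, p_adj
    d0: float
    s0_sq: float
    cohort_id: str


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-F prior for residual variances.

    Returns (d0, s0^2); d0 may be inf when variances are essentially
    homogeneous, and nan when the fit is impossible (e.g. one feature).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.nan, np.nan
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    target = e_var - special.polygamma(1, df / 2.0)
    if not np.isfinite(target):
        return np.nan, np.nan
    if target <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t(dataset: ExpressionDataset, d0_override: float | None = None) -> DEResult:
    """Empirical-Bayes moderated two-sample t per feature.

    logFC is mean(case) - mean(control); residual variances are shrunk
    toward a prior fitted by matching the moments of log s^2 through
    digamma/trigamma equations; t uses d0 + d degrees of freedom.  When
    the prior cannot be fit (single feature, degenerate variances) the
    ordinary pooled t is used and a warning logged.  ``d0_override``
    injects a fixed prior df (used to verify the shrinkage limits).
    """
    dataset.require_two_per_group()
    x = dataset.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise FormatError("moderated t cannot handle masked values")
    case = dataset.case_mask()
    n1, n2 = int((~case).sum()), int(case.sum())
    x_ctl, x_case = x[:, ~case], x[:, case]
    logfc = x_case.mean(axis=1) - x_ctl.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((x_ctl - x_ctl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_case - x_case.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    if np.all(s2 <= 0):
        raise FormatError("zero residual variance in every feature")

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.exp(np.mean(np.log(s2[s2 > 0]))))
    else:
        d0, s0_sq = _fit_f_dist(s2, df_resid)
    if not np.isfinite(d0) and not np.isinf(d0):
        logger.warning(
            "cohort %s: prior df estimate non-finite; falling back to ordinary t",
            dataset.cohort_id,
        )
        d0, s0_sq = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t_mod": t_mod,
            "df": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=dataset.values.index,
    )
    return DEResult(table=table, d0=d0, s0_sq=s0_sq, cohort_id=dataset.cohort_id)


# ---------------------------------------------------------------------------
# combination


def fisher_combine(p_values: list[float]) -> tuple[float, int, float]:
    """Fisher's method: X2 = -2 sum(ln p), p from chi2 with 2k df.

    Zero p-values are clamped to 1e-300 with a warning.  Returns
    (X2, k, combined p).
    """
    p = np.asarray([v for v in p_values if np.isfinite(v)], dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p = 0 encountered; clamping to %g", P_FLOOR)
        p = np.maximum(p, P_FLOOR)
    x2 = float(-2.0 * np.log(p).sum())
    k = int(p.size)
    return x2, k, float(stats.chi2.sf(x2, 2 * k))


def combined_t(t_values: list[float]) -> tuple[float, int]:
    """Plain sum of per-cohort moderated t; sign gives the direction."""
    t = np.asarray(t_values, dtype=float)
    if t.size == 0:
        raise ValueError("no t-statistics to combine")
    total = float(t.sum())
    return total, int(np.sign(total))


# ---------------------------------------------------------------------------
# orchestration


def run_meta(
    datasets: list[ExpressionDataset],
    alpha: float = 0.05,
    combine_on: str = "p",
    min_cohorts: int | None = None,
    batch: pd.Series | None = None,
    apply_combat: bool = False,
) -> pd.DataFrame:
    """Normalize, test, and combine cohorts into a MetaResultTable.

    Features are kept if measured in at least ``min_cohorts`` cohorts
    (default: 2, or 1 when only one cohort is supplied).  Columns:
    per-cohort t/p, ``k``, ``T_comb``, ``X2``, ``p_comb``,
    ``p_comb_adj``, ``direction``, ``significant``; plus ``logFC_mean``
    across measuring cohorts.
    """
    if not datasets:
        raise ValueError("at least one cohort required")
    if combine_on not in ("p", "p_adj"):
        raise ValueError("combine_on must be 'p' or 'p_adj'")
    if min_cohorts is None:
        min_cohorts = 2 if len(datasets) > 1 else 1

    processed = []
    for ds in datasets:
        ds = preprocess(ds)
        if apply_combat and batch is not None:
            ds = combat_adjust(ds, batch)
        processed.append(ds)
    results = [moderated_t(ds) for ds in processed]

    counts: dict[str, int] = {}
    for res in results:
        for f in res.table.index:
            counts[f] = counts.get(f, 0) + 1
    features = [f for f, c in counts.items() if c >= min_cohorts]
    if not features:
        raise FormatError("no features overlap across cohorts")

    per_cohort = {}
    rows = {
        "k": [], "T_comb": [], "X2": [], "p_comb": [], "direction": [],
        "logFC_mean": [],
    }
    for res in results:
        per_cohort[f"t_{res.cohort_id}"] = res.table["t_mod"].reindex(features)
        per_cohort[f"p_{res.cohort_id}"] = res.table["p"].reindex(features)
    for f in features:
        ps, ts, fcs = [], [], []
        for res in results:
            if f in res.table.index:
                row = res.table.loc[f]
                ps.append(row["p_adj" if combine_on == "p_adj" else "p"])
                ts.append(row["t_mod"])
                fcs.append(row["logFC"])
        x2, k, p_comb = fisher_combine(ps)
        t_comb, direction = combined_t(ts)
        rows["k"].append(k)
        rows["T_comb"].append(t_comb)
        rows["X2"].append(x2)
        rows["p_comb"].append(p_comb)
        rows["direction"].append(direction)
        rows["logFC_mean"].append(float(np.mean(fcs)))

    table = pd.DataFrame(rows, index=pd.Index(features, name="feature"))
    for name, series in per_cohort.items():
        table[name] = series
    table["p_comb_adj"] = bh_adjust(table["p_comb"].to_numpy())
    table["significant"] = table["p_comb"] < alpha
    return table
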