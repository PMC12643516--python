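"""Sponge-network construction and regulatory-triad assembly.

An lncRNA-miRNA (or miRNA-mRNA 3'-UTR) edge is admitted when the
target carries at least one seed site of the required class and the
best duplex energy over the site +- flank window reaches the MFE
threshold.  miRNAs are ranked by degree (number of lncRNA partners);
triad candidates pair each hub lncRNA with its edge miRNAs and their
edge mRNAs, keep direction-consistent triples (lncRNA up, miRNA down,
mRNA up — or the global mirror, which is labelled), and rank them by
the mean of three evidence ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .duplex import (
    SITE_CLASS_RANK,
    SeedSite,
    best_site_mfe,
    load_nn_params,
    scan_seed_sites,
)

__all__ = [
    "SpongeNetwork",
    "TriadCandidate",
    "build_sponge_network",
    "rank_mirnas",
    "assemble_triads",
]

_SITE_COLS = ["n_8mer", "n_7mer_m8", "n_7mer_A1", "n_6mer"]
_CLASS_TO_COL = {"8mer": "n_8mer", "7mer-m8": "n_7mer_m8",
                 "7mer-A1": "n_7mer_A1", "6mer": "n_6mer"}


@dataclass
class SpongeNetwork:
    """Bipartite seed/energy-evidence networks and miRNA degrees.

    Edge tables carry (source, target, best_mfe_kcal_mol, site counts
    by class); ``degree`` counts distinct lncRNA partners per miRNA.
    """

    lncrna_mirna_edges: pd.DataFrame
    mirna_mrna_edges: pd.DataFrame
    degree: pd.Series
    mfe_threshold: float
    min_site_class: str
    pairings: dict[tuple[str, str], str]

    @property
    def n_edges(self) -> int:
        return len(self.lncrna_mirna_edges) + len(self.mirna_mrna_edges)


def _empty_edges(kind: str) -> pd.DataFrame:
    return pd.DataFrame(
        columns=["type", "source", "target", "best_mfe_kcal_mol", *_SITE_COLS]
    ).astype({"best_mfe_kcal_mol": float, **{c: int for c in _SITE_COLS}})


def _scan_pairs(
    targets: dict[str, str],
    mirnas: dict[str, str],
    kind: str,
    mfe_threshold: float,
    min_rank: int,
    params: dict,
    flank: int,
    pairings: dict[tuple[str, str], str],
) -> pd.DataFrame:
    rows = []
    for target_id in sorted(targets):
        tseq = targets[target_id]
        for mirna_id in sorted(mirnas):
            sites = scan_seed_sites(tseq, mirnas[mirna_id], target_id, mirna_id)
            qualifying = [s for s in sites if SITE_CLASS_RANK[s.site_class] >= min_rank]
            if not qualifying:
                continue
            best_mfe, best_pairing = 0.0, ""
            counts = dict.fromkeys(_SITE_COLS, 0)
            for site in qualifying:
                counts[_CLASS_TO_COL[site.site_class]] += 1
                result = best_site_mfe(tseq, site, mirnas[mirna_id], params=params, flank=flank)
                if result.mfe < best_mfe:
                    best_mfe, best_pairing = result.mfe, result.pairing
            if best_mfe <= mfe_threshold:
                if kind == "lncrna-mirna":
                    source, target = target_id, mirna_id
                else:
                    source, target = mirna_id, target_id
                rows.append({"type": kind, "source": source, "target": target,
                             "best_mfe_kcal_mol": best_mfe, **counts})
                pairings[(source, target)] = best_pairing
    if not rows:
        return _empty_edges(kind)
    edges = pd.DataFrame(rows)
    return edges.sort_values(["source", "target"], kind="stable").reset_index(drop=True)


def build_sponge_network(
    lncrna_seqs: dict[str, str],
    mirna_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    mfe_threshold: float = -20.0,
    min_site_class: str = "7mer-m8",
    flank: int = 15,
    params: dict | None = None,
) -> SpongeNetwork:
    """Assemble the lncRNA-miRNA and miRNA-mRNA evidence networks.

    Callers restrict the sequence dictionaries to meta-significant
    candidates; this function only evaluates sequence evidence.  Output
    ordering is deterministic (sorted ids).
    """
    if min_site_class not in SITE_CLASS_RANK:
        raise ValueError(f"unknown site class {min_site_class!r}")
    if params is None:
        params = load_nn_params()
    min_rank = SITE_CLASS_RANK[min_site_class]
    pairings: dict[tuple[str, str], str] = {}
    lnc_edges = _scan_pairs(
        lncrna_seqs, mirna_seqs, "lncrna-mirna", mfe_threshold, min_rank,
        params, flank, pairings,
    )
    mrna_edges = _scan_pairs(
        utr_seqs, mirna_seqs, "mirna-mrna", mfe_threshold, min_rank,
        params, flank, pairings,
    )
    if len(lnc_edges):
        degree = lnc_edges.groupby("target")["source"].nunique()
    else:
        degree = pd.Series(dtype=int)
    degree = degree.reindex(sorted(mirna_seqs), fill_value=0).astype(int)
    degree.name = "degree"
    return SpongeNetwork(
        lncrna_mirna_edges=lnc_edges,
        mirna_mrna_edges=mrna_edges,
        degree=degree,
        mfe_threshold=mfe_threshold,
        min_site_class=min_site_class,
        pairings=pairings,
    )


def rank_mirnas(network: SpongeNetwork) -> pd.DataFrame:
    """miRNAs by descending lncRNA-partner degree.

    Ties break by better (lower) best MFE over the miRNA's lncRNA
    edges, then lexicographic id.
    """
    if not len(network.lncrna_mirna_edges):
        return pd.DataFrame(columns=["mirna", "degree", "best_mfe_kcal_mol"])
    best_mfe = network.lncrna_mirna_edges.groupby("target")["best_mfe_kcal_mol"].min()
    table = pd.DataFrame({
        "mirna": best_mfe.index,
        "degree": network.degree.reindex(best_mfe.index).to_numpy(),
        "best_mfe_kcal_mol": best_mfe.to_numpy(),
    })
    return table.sort_values(
        ["degree", "best_mfe_kcal_mol", "mirna"],
        ascending=[False, True, True], kind="stable",
    ).reset_index(drop=True)


@dataclass
class TriadCandidate:
    """One (lncRNA, miRNA, mRNA) candidate with its evidence trail."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    direction_ok: bool
    mirrored: bool
    hub_k_within: float
    mirna_degree: int
    mrna_abs_t_comb: float
    lnc_mir_mfe: float
    mir_mrna_mfe: float
    composite_rank: float


def assemble_triads(
    hubs: pd.DataFrame,
    network: SpongeNetwork,
    meta_lnc: pd.DataFrame,
    meta_mir: pd.DataFrame,
    meta_mrna: pd.DataFrame,
    top_n: int = 10,
) -> pd.DataFrame:
    """Assemble and rank direction-consistent triad candidates.

    The canonical direction is lncRNA up (T_comb > 0), miRNA down
    (T_comb < 0), mRNA up (T_comb > 0); the global mirror (all signs
    flipped) is also accepted and labelled ``mirrored``.  The composite
    rank is the mean of the ranks of hub intramodular connectivity,
    miRNA degree, and mRNA |T_comb| (1 = best); candidates sort by
    composite rank with a deterministic id tie-break.
    """
    lnc_edges = network.lncrna_mirna_edges
    mrna_edges = network.mirna_mrna_edges
    candidates = []
    for _, hub_row in hubs.dropna(subset=["hub"]).iterrows():
        lnc = hub_row["hub"]
        if lnc not in meta_lnc.index:
            continue
        t_lnc = float(meta_lnc.loc[lnc, "T_comb"])
        for _, e1 in lnc_edges[lnc_edges["source"] == lnc].iterrows():
            mir = e1["target"]
            if mir not in meta_mir.index:
                continue
            t_mir = float(meta_mir.loc[mir, "T_comb"])
            for _, e2 in mrna_edges[mrna_edges["source"] == mir].iterrows():
                mrna = e2["target"]
                if mrna not in meta_mrna.index:
                    continue
                t_mrna = float(meta_mrna.loc[mrna, "T_comb"])
                canonical = t_lnc > 0 and t_mir < 0 and t_mrna > 0
                mirrored = t_lnc < 0 and t_mir > 0 and t_mrna < 0
                if not (canonical or mirrored):
                    continue
                candidates.append({
                    "lncrna_id": lnc,
                    "mirna_id": mir,
                    "mrna_id": mrna,
                    "direction_ok": True,
                    "mirrored": mirrored,
                    "hub_k_within": float(hub_row["k_within"]),
                    "mirna_degree": int(network.degree.get(mir, 0)),
                    "mrna_abs_t_comb": abs(t_mrna),
                    "lnc_mir_mfe": float(e1["best_mfe_kcal_mol"]),
                    "mir_mrna_mfe": float(e2["best_mfe_kcal_mol"]),
                })
    if not candidates:
        return pd.DataFrame(columns=[
            "lncrna_id", "mirna_id", "mrna_id", "direction_ok", "mirrored",
            "hub_k_within", "mirna_degree", "mrna_abs_t_comb",
            "lnc_mir_mfe", "mir_mrna_mfe", "composite_rank",
        ])
    table = pd.DataFrame(candidates)
    table["composite_rank"] = (
        table["hub_k_within"].rank(ascending=False, method="min")
        + table["mirna_degree"].rank(ascending=False, method="min")
        + table["mrna_abs_t_comb"].rank(ascending=False, method="min")
    ) / 3.0
    table = table.sort_values(
        ["composite_rank", "lncrna_id", "mirna_id", "mrna_id"], kind="stable"
    ).reset_index(drop=True)
    return table.head(top_n)
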