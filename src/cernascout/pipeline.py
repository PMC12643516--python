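"""End-to-end orchestration: simulate -> meta (x3 panels) -> coexpression
-> sponge network -> triads -> enrichment.

``run_all`` drives every stage from one :class:`PipelineConfig`, writes
every intermediate as a plain text file, and records provenance (config
echo, input hashes, per-stage feature counts).  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import coexpression as coex
from . import io as cio
from . import meta as cmeta
from .datasets import ExpressionDataset, GeneSetCollection
from .enrichment import ora_table
from .simulate import SimulationConfig, simulate_all
from .sponge import build_sponge_network, rank_mirnas, assemble_triads

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "run_from_simulation"]


@dataclass
class PipelineConfig:
    """All stage parameters plus either a simulation block or file paths."""

    rng_seed: int = 0
    alpha: float = 0.05
    combine_on_mrna: str = "p"
    combine_on_mirna: str = "p_adj"
    combine_on_lncrna: str = "p_adj"
    beta: float | str = 6          # soft threshold; "auto" sweeps candidates
    min_module_size: int = 30
    deep_split: int = 2
    edge_cutoff: float = 0.1
    outlier_cut_frac: float = 0.75
    mfe_threshold: float = -20.0
    min_site_class: str = "7mer-m8"
    top_n: int = 10
    simulate: dict | None = None   # SimulationConfig overrides; None => file inputs
    cohorts_mrna: list[tuple[str, str]] = field(default_factory=list)
    cohorts_mirna: list[tuple[str, str]] = field(default_factory=list)
    lncrna_fasta: str | None = None
    utr_fasta: str | None = None
    mirna_fasta: str | None = None
    gene_sets_gmt: str | None = None

    def validate(self) -> None:
        if self.deep_split not in coex.DEEP_SPLIT_Q:
            raise ValueError(f"deep_split must be in {sorted(coex.DEEP_SPLIT_Q)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.simulate is None:
            if not self.cohorts_mrna:
                raise ValueError("config missing mRNA cohorts")
            if not self.cohorts_mirna:
                raise ValueError("config missing miRNA cohorts")
            for path in [self.lncrna_fasta, self.utr_fasta, self.mirna_fasta]:
                if path is None:
                    raise ValueError("config missing a FASTA input (lncRNA/UTR/miRNA panel)")
                if not Path(path).exists():
                    raise FileNotFoundError(path)
            for matrix, labels in [*self.cohorts_mrna, *self.cohorts_mirna]:
                for p in (matrix, labels):
                    if not Path(p).exists():
                        raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.cohorts_mrna = [tuple(c) for c in cfg.cohorts_mrna]
        cfg.cohorts_mirna = [tuple(c) for c in cfg.cohorts_mirna]
        return cfg


@dataclass
class PipelineResult:
    """In-memory pipeline outputs (also written to disk when requested)."""

    meta_mrna: pd.DataFrame
    meta_lncrna: pd.DataFrame
    meta_mirna: pd.DataFrame
    fit_table: pd.DataFrame
    partition: coex.ModulePartition
    hubs: pd.DataFrame
    network: object
    mirna_ranking: pd.DataFrame
    triads: pd.DataFrame
    ora: pd.DataFrame
    counts: dict
    truth: object | None = None


def _meta_panel(cohorts: list[ExpressionDataset], biotype: str, alpha: float,
                combine_on: str) -> pd.DataFrame:
    subsets = []
    for ds in cohorts:
        if (ds.biotype == biotype).any():
            subsets.append(ds.subset_biotype(biotype))
    if not subsets:
        raise ValueError(f"no cohort measures any {biotype} feature")
    return cmeta.run_meta(subsets, alpha=alpha, combine_on=combine_on)


def run_from_simulation(
    sim_config: SimulationConfig, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full discovery pipeline on freshly simulated data."""
    config = config or PipelineConfig(rng_seed=sim_config.rng_seed)
    cohorts, mir_cohorts, lnc_fa, utr_fa, mir_fa, truth = simulate_all(sim_config)
    result = _run_stages(cohorts, mir_cohorts, lnc_fa, utr_fa, mir_fa, None, config)
    result.truth = truth
    return result


def _run_stages(
    cohorts: list[ExpressionDataset],
    mir_cohorts: list[ExpressionDataset],
    lnc_fa: dict[str, str],
    utr_fa: dict[str, str],
    mir_fa: dict[str, str],
    gene_sets: GeneSetCollection | None,
    config: PipelineConfig,
) -> PipelineResult:
    counts: dict[str, dict] = {}

    # --- meta-analysis, one panel at a time
    meta_mrna = _meta_panel(cohorts, "mRNA", config.alpha, config.combine_on_mrna)
    meta_lnc = _meta_panel(cohorts, "lncRNA", config.alpha, config.combine_on_lncrna)
    meta_mir = _meta_panel(mir_cohorts, "miRNA", config.alpha, config.combine_on_mirna)
    counts["meta"] = {
        "mrna_tested": len(meta_mrna), "mrna_significant": int(meta_mrna["significant"].sum()),
        "lncrna_tested": len(meta_lnc), "lncrna_significant": int(meta_lnc["significant"].sum()),
        "mirna_tested": len(meta_mir), "mirna_significant": int(meta_mir["significant"].sum()),
    }
    logger.info("meta-analysis: %s", counts["meta"])

    # --- coexpression on the pooled mixed lncRNA+mRNA matrix: all cohorts
    # measuring lncRNAs, quantile-normalized and concatenated sample-wise
    # (normalization aligns the per-cohort intensity distributions, so the
    # pooled matrix is free of additive cohort offsets)
    lnc_cohorts = [ds for ds in cohorts if (ds.biotype == "lncRNA").any()]
    if not lnc_cohorts:
        raise ValueError("no cohort measures lncRNA features for coexpression")
    processed = [cmeta.preprocess(ds) for ds in lnc_cohorts]
    shared = processed[0].values.index
    for ds in processed[1:]:
        shared = shared.intersection(ds.values.index)
    coexpr_cohort = ExpressionDataset(
        values=pd.concat([ds.values.loc[shared] for ds in processed], axis=1),
        biotype=processed[0].biotype.loc[shared],
        group=pd.concat([ds.group for ds in processed]),
        cohort_id="pooled",
        is_log=True,
    )
    coexpr_cohort, removed = coex.remove_outlier_samples(
        coexpr_cohort, cut_height_frac=config.outlier_cut_frac
    )
    if config.beta == "auto":
        beta, fit_table = coex.pick_soft_threshold(coexpr_cohort)
    else:
        beta = float(config.beta)
        fit_table = pd.DataFrame()
    adjacency = coex.correlation_adjacency(coexpr_cohort, beta)
    tom = coex.tom_similarity(adjacency)
    partition = coex.detect_modules(
        tom, min_module_size=config.min_module_size, deep_split=config.deep_split
    )
    coex.module_eigengene(coexpr_cohort, partition)
    k_within = coex.intramodular_connectivity(adjacency, partition)
    hubs = coex.select_hub_lncrna(
        partition, k_within, coexpr_cohort.biotype, meta_table=meta_lnc,
        adjacency=adjacency, edge_cutoff=config.edge_cutoff,
    )
    counts["coexpression"] = {
        "samples_removed": len(removed), "beta": beta,
        "n_modules": len(partition.module_ids),
        "unassigned": int((partition.labels == 0).sum()),
    }
    logger.info("coexpression: %s", counts["coexpression"])

    # --- sponge network on meta-significant candidates
    sig_lnc = set(meta_lnc.index[meta_lnc["significant"]])
    sig_mrna = set(meta_mrna.index[meta_mrna["significant"]])
    lnc_candidates = {k: v for k, v in lnc_fa.items() if k in sig_lnc}
    utr_candidates = {k: v for k, v in utr_fa.items() if k in sig_mrna}
    network = build_sponge_network(
        lnc_candidates, mir_fa, utr_candidates,
        mfe_threshold=config.mfe_threshold,
        min_site_class=config.min_site_class,
    )
    mirna_ranking = rank_mirnas(network)
    counts["sponge"] = {
        "lncrna_candidates": len(lnc_candidates),
        "mrna_candidates": len(utr_candidates),
        "lncrna_mirna_edges": len(network.lncrna_mirna_edges),
        "mirna_mrna_edges": len(network.mirna_mrna_edges),
    }
    logger.info("sponge network: %s", counts["sponge"])

    # --- triads
    triads = assemble_triads(
        hubs, network, meta_lnc, meta_mir, meta_mrna, top_n=config.top_n
    )
    counts["triads"] = {"candidates_reported": len(triads)}
    logger.info("triads: %s", counts["triads"])

    # --- enrichment: supplied gene sets, else module-membership sets
    if gene_sets is None:
        sets = {}
        for module_id in partition.module_ids:
            members = [m for m in partition.members(module_id)]
            if members:
                sets[f"module_{module_id}"] = (f"coexpression module {module_id}", members)
        gene_sets = GeneSetCollection(sets=sets) if sets else None
    if gene_sets is not None and len(gene_sets) and len(sig_mrna | sig_lnc):
        universe = list(meta_mrna.index) + list(meta_lnc.index)
        ora = ora_table(sig_mrna | sig_lnc, gene_sets, universe)
    else:
        ora = pd.DataFrame()
    counts["enrichment"] = {"sets_tested": len(ora)}

    return PipelineResult(
        meta_mrna=meta_mrna, meta_lncrna=meta_lnc, meta_mirna=meta_mir,
        fit_table=fit_table, partition=partition, hubs=hubs, network=network,
        mirna_ranking=mirna_ranking, triads=triads, ora=ora, counts=counts,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run every stage and write all artifacts under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_hashes = {}
    if config.simulate is not None:
        sim_config = SimulationConfig(**{"rng_seed": config.rng_seed, **config.simulate})
        cohorts, mir_cohorts, lnc_fa, utr_fa, mir_fa, truth = simulate_all(sim_config)
        gene_sets = (
            cio.read_gmt(config.gene_sets_gmt) if config.gene_sets_gmt else None
        )
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    else:
        truth = None
        cohorts = [
            cio.read_expression_tsv(m, l, biotype=_guess_biotype_sidecar(m), cohort_id=Path(m).stem)
            for m, l in config.cohorts_mrna
        ]
        mir_cohorts = [
            cio.read_expression_tsv(m, l, biotype="miRNA", cohort_id=Path(m).stem)
            for m, l in config.cohorts_mirna
        ]
        lnc_fa = cio.read_fasta(config.lncrna_fasta)
        utr_fa = cio.read_fasta(config.utr_fasta)
        mir_fa = cio.read_fasta(config.mirna_fasta)
        gene_sets = cio.read_gmt(config.gene_sets_gmt) if config.gene_sets_gmt else None
        for m, l in [*config.cohorts_mrna, *config.cohorts_mirna]:
            input_hashes[str(m)] = _sha256(Path(m))
            input_hashes[str(l)] = _sha256(Path(l))
        for p in [config.lncrna_fasta, config.utr_fasta, config.mirna_fasta]:
            input_hashes[str(p)] = _sha256(Path(p))

    result = _run_stages(cohorts, mir_cohorts, lnc_fa, utr_fa, mir_fa, gene_sets, config)
    result.truth = truth

    comment = f"ceRNAscout seed={config.rng_seed}"
    cio.write_table(result.meta_mrna.reset_index(), out / "meta_mrna.tsv", comment)
    cio.write_table(result.meta_lncrna.reset_index(), out / "meta_lncrna.tsv", comment)
    cio.write_table(result.meta_mirna.reset_index(), out / "meta_mirna.tsv", comment)
    if len(result.fit_table):
        cio.write_table(result.fit_table, out / "soft_threshold_fit.tsv", comment)
    cio.write_table(
        result.partition.labels.rename("module").rename_axis("feature").reset_index(),
        out / "modules.tsv", comment,
    )
    cio.write_table(
        result.partition.eigengenes.reset_index(names="sample"),
        out / "eigengenes.tsv", comment,
    )
    cio.write_table(result.hubs, out / "hubs.tsv", comment)
    edges = pd.concat(
        [result.network.lncrna_mirna_edges, result.network.mirna_mrna_edges],
        ignore_index=True,
    )
    cio.write_table(edges, out / "sponge_edges.tsv", comment)
    with open(out / "sponge_pairings.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tpairing\n")
        for (src, tgt), pairing in sorted(result.network.pairings.items()):
            fh.write(f"{src}\t{tgt}\t{pairing}\n")
    cio.write_table(result.mirna_ranking, out / "mirna_ranking.tsv", comment)
    cio.write_table(result.triads, out / "triads.tsv", comment)
    if len(result.ora):
        cio.write_table(result.ora, out / "ora.tsv", comment)

    provenance = {
        "config": {k: v for k, v in asdict(config).items()},
        "input_sha256": input_hashes,
        "stage_counts": result.counts,
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
    return result


def _guess_biotype_sidecar(matrix_path: str) -> str | Path:
    sidecar = Path(matrix_path).with_suffix(".biotype.tsv")
    return sidecar if sidecar.exists() else "mRNA"
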