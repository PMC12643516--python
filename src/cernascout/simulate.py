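"""Synthetic multi-cohort expression data with a planted ceRNA triad.

The generator emulates the statistical structure a ceRNA discovery
pipeline has to detect:

* D independent case/control cohorts over a shared mRNA + lncRNA
  universe, each sample drawn from a Gaussian latent-factor model

      x_gs = mu_g + lambda_g * f_{m(g),s} + delta_g * c_s + b_d + eps_gs

  with one latent factor f per coexpression module (shared by a
  module's members within a sample, independent across samples),
  a case indicator c_s in {0, 1}, an additive per-cohort batch offset
  b_d, and i.i.d. Gaussian noise eps ~ N(0, sigma^2);
* a planted hub lncRNA that carries a larger loading than its module
  mates (so it has the highest intramodular connectivity) and a
  positive log2 fold change;
* a planted down-regulated miRNA measured in separate miRNA cohorts;
* a planted up-regulated mRNA;
* transcript sequences (uniform random RNA) into which seed-match
  sites for the planted miRNA, embedded in an extended complementary
  stretch, are inserted at recorded coordinates.

Module membership and differential expression are orthogonal except
for the planted triad, which carries both — this isolates what the
coexpression and meta-analysis stages each have to detect.  All
randomness flows from ``SimulationConfig.rng_seed`` through a single
``numpy.random.Generator``; identical config implies bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .duplex import reverse_complement

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression_cohorts",
    "simulate_mirna_cohorts",
    "simulate_transcripts",
    "simulate_all",
]


class ConfigurationError(ValueError):
    """Simulation parameters are mutually inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference study conditions: 2000 mRNAs and
    100 lncRNAs measured in 8 case/control cohorts of 50+50 samples,
    50 miRNAs in 2 cohorts, five latent coexpression modules, loading
    0.8 (hub 1.2), planted log2 fold change +-1 against unit noise,
    and two 8mer seed sites planted in the hub lncRNA and the target
    mRNA 3'-UTR.
    """

    n_mrna: int = 2000
    n_lncrna: int = 100
    n_mirna: int = 50
    n_cohorts_mrna: int = 8
    n_cohorts_mirna: int = 2
    samples_per_group: int = 50
    n_modules: int = 5
    module_size_range: tuple[int, int] = (30, 60)
    loading_scale: float = 0.8
    hub_loading: float = 1.2
    de_effect: float = 1.0
    noise_sd: float = 1.0
    batch_shift: float = 0.5
    frac_de: float = 0.1
    transcript_len: int = 500
    mirna_len: int = 22
    n_planted_sites: int = 2
    n_decoy_lncrnas: int = 3
    baseline_mean: float = 7.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna,
            "n_mirna": self.n_mirna,
            "n_cohorts_mrna": self.n_cohorts_mrna,
            "n_cohorts_mirna": self.n_cohorts_mirna,
            "samples_per_group": self.samples_per_group,
            "n_modules": self.n_modules,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        lo, hi = self.module_size_range
        if lo < 3 or hi < lo:
            raise ConfigurationError(
                f"module_size_range must satisfy 3 <= min <= max, got {self.module_size_range}"
            )
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError(f"frac_de must lie in [0, 1], got {self.frac_de}")
        if self.transcript_len < 30:
            raise ConfigurationError(
                f"transcript_len must be >= 30, got {self.transcript_len}"
            )
        if self.n_modules * hi > self.n_mrna + self.n_lncrna:
            raise ConfigurationError(
                "module_size_range inconsistent with feature universe: "
                f"{self.n_modules} modules of up to {hi} features exceed "
                f"{self.n_mrna + self.n_lncrna} mRNA+lncRNA features"
            )
        if self.mirna_len < 8:
            raise ConfigurationError(f"mirna_len must be >= 8, got {self.mirna_len}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_size_range"] = list(self.module_size_range)
        return d


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    module_assignment: dict[str, int] = field(default_factory=dict)
    planted_hub_lncrna: str = ""
    planted_mirna: str = ""
    planted_mrna: str = ""
    decoy_lncrnas: list[str] = field(default_factory=list)
    de_table: dict[str, float] = field(default_factory=dict)
    # (transcript id, start, end, site class); 0-based half-open
    planted_sites: list[tuple[str, int, int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "module_assignment": dict(self.module_assignment),
            "planted_hub_lncrna": self.planted_hub_lncrna,
            "planted_mirna": self.planted_mirna,
            "planted_mrna": self.planted_mrna,
            "decoy_lncrnas": list(self.decoy_lncrnas),
            "de_table": dict(self.de_table),
            "planted_sites": [list(site) for site in self.planted_sites],
        }


def _feature_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    mrna = [f"mRNA:G{i:05d}" for i in range(config.n_mrna)]
    lnc = [f"lncRNA:L{i:04d}" for i in range(config.n_lncrna)]
    mir = [f"miRNA:M{i:03d}" for i in range(config.n_mirna)]
    return mrna, lnc, mir


def _plan_truth(config: SimulationConfig, rng: np.random.Generator) -> tuple[GroundTruth, dict]:
    """Draw module memberships, loadings and true effects once.

    The same plan is reused by the expression, miRNA, and transcript
    generators so their outputs are mutually consistent.
    """
    mrna_ids, lnc_ids, mir_ids = _feature_ids(config)
    features = mrna_ids + lnc_ids

    # module sizes and membership: each module gets mostly mRNAs plus a
    # few lncRNAs; the planted hub lncRNA lives in module 1
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    assignment: dict[str, int] = {f: 0 for f in features}
    mrna_pool = list(rng.permutation(mrna_ids))
    lnc_pool = list(rng.permutation(lnc_ids))
    hub = lnc_pool.pop(0)
    loadings: dict[str, float] = {f: 0.0 for f in features}
    for module_id, size in enumerate(sizes, start=1):
        n_lnc = min(3, len(lnc_pool), size - 1)
        members = [mrna_pool.pop() for _ in range(size - n_lnc)]
        members += [lnc_pool.pop() for _ in range(n_lnc)]
        if module_id == 1:
            members.append(hub)
        for f in members:
            assignment[f] = module_id
            loadings[f] = config.loading_scale
    loadings[hub] = config.hub_loading
    assignment[hub] = 1

    # differential expression: frac_de of features are DE with random sign
    # and heterogeneous magnitude U(0.3, 0.8) x de_effect; the planted
    # triad members carry the full +-de_effect, i.e. they are the headline
    # genes of the study, the way the triad mRNA is the top combined-T
    # gene in the design this emulates
    de: dict[str, float] = {}
    n_de = int(round(config.frac_de * len(features)))
    de_features = rng.choice(len(features), size=n_de, replace=False) if n_de else []
    for idx in de_features:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de[features[idx]] = sign * config.de_effect * rng.uniform(0.3, 0.8)
    # planted mRNA: a module-1 member so coexpression and DE coincide
    module1_mrnas = [f for f, m in assignment.items() if m == 1 and f.startswith("mRNA:")]
    planted_mrna = module1_mrnas[int(rng.integers(len(module1_mrnas)))]
    de[hub] = abs(config.de_effect)
    de[planted_mrna] = abs(config.de_effect)

    # miRNA effects
    n_de_mir = int(round(config.frac_de * config.n_mirna))
    de_mirs = rng.choice(config.n_mirna, size=n_de_mir, replace=False) if n_de_mir else []
    for idx in de_mirs:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de[mir_ids[idx]] = sign * config.de_effect * rng.uniform(0.3, 0.8)
    planted_mirna = mir_ids[int(rng.integers(config.n_mirna))]
    de[planted_mirna] = -abs(config.de_effect)

    # decoy sponge partners: a few further differentially expressed
    # lncRNAs carry one site for the planted miRNA, making it a
    # top-degree node of the sponge network (ceRNA hubs typically have
    # several predicted lncRNA partners, not one)
    other_lncs = [l for l in lnc_ids if l != hub]
    n_decoys = min(config.n_decoy_lncrnas, len(other_lncs))
    decoy_idx = rng.choice(len(other_lncs), size=n_decoys, replace=False) if n_decoys else []
    decoys = [other_lncs[i] for i in decoy_idx]
    for d in decoys:
        if d not in de:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            de[d] = sign * config.de_effect * rng.uniform(0.3, 0.8)

    truth = GroundTruth(
        module_assignment=assignment,
        planted_hub_lncrna=hub,
        planted_mirna=planted_mirna,
        planted_mrna=planted_mrna,
        decoy_lncrnas=decoys,
        de_table=de,
    )
    plan = {
        "mrna_ids": mrna_ids,
        "lnc_ids": lnc_ids,
        "mir_ids": mir_ids,
        "loadings": loadings,
    }
    return truth, plan


def _simulate_cohort(
    feature_ids: list[str],
    biotypes: pd.Series,
    assignment: dict[str, int],
    loadings: dict[str, float],
    de: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    cohort_id: str,
    batch_offset: float,
    n_modules: int,
) -> ExpressionDataset:
    n = len(feature_ids)
    n_samples = 2 * config.samples_per_group
    case = np.zeros(n_samples)
    case[config.samples_per_group:] = 1.0
    lam = np.array([loadings.get(f, 0.0) for f in feature_ids])
    mod = np.array([assignment.get(f, 0) for f in feature_ids])
    delta = np.array([de.get(f, 0.0) for f in feature_ids])

    factors = rng.standard_normal((n_modules + 1, n_samples))  # row 0 unused
    # center factors within each group: module membership is exactly
    # orthogonal to case/control, so with sigma=0 the realized mean
    # difference equals delta for every feature
    for mask in (case == 0, case == 1):
        factors[:, mask] -= factors[:, mask].mean(axis=1, keepdims=True)
    eps = config.noise_sd * rng.standard_normal((n, n_samples))
    x = (
        config.baseline_mean
        + lam[:, None] * factors[mod, :] * (mod > 0)[:, None]
        + delta[:, None] * case[None, :]
        + batch_offset
        + eps
    )
    sample_ids = [f"{cohort_id}_ctl{i:03d}" for i in range(config.samples_per_group)]
    sample_ids += [f"{cohort_id}_cad{i:03d}" for i in range(config.samples_per_group)]
    values = pd.DataFrame(x, index=feature_ids, columns=sample_ids)
    group = pd.Series(
        ["control"] * config.samples_per_group + ["case"] * config.samples_per_group,
        index=sample_ids,
    )
    return ExpressionDataset(
        values=values, biotype=biotypes, group=group, cohort_id=cohort_id, is_log=True
    )


def simulate_expression_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate the mRNA+lncRNA case/control cohorts and ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    truth, plan = _plan_truth(config, rng)
    features = plan["mrna_ids"] + plan["lnc_ids"]
    biotypes = pd.Series(
        ["mRNA"] * len(plan["mrna_ids"]) + ["lncRNA"] * len(plan["lnc_ids"]),
        index=features,
    )
    batch = config.batch_shift * rng.standard_normal(config.n_cohorts_mrna)
    cohorts = [
        _simulate_cohort(
            features,
            biotypes,
            truth.module_assignment,
            plan["loadings"],
            truth.de_table,
            config,
            rng,
            f"cohortE{d + 1}",
            batch[d],
            config.n_modules,
        )
        for d in range(config.n_cohorts_mrna)
    ]
    return cohorts, truth


def simulate_mirna_cohorts(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate the miRNA case/control cohorts.

    miRNA panels carry no latent modules; only the case effect, batch
    offset and noise.  The planted miRNA is down-regulated (delta < 0).
    """
    # derive a distinct stream so miRNA noise is independent of the
    # expression cohorts while staying a pure function of the seed
    rng = np.random.default_rng([config.rng_seed, 104729])
    if truth is None:
        plan_rng = np.random.default_rng(config.rng_seed)
        truth, _ = _plan_truth(config, plan_rng)
    _, _, mir_ids = _feature_ids(config)
    biotypes = pd.Series("miRNA", index=mir_ids)
    no_modules = {f: 0 for f in mir_ids}
    no_loadings = {f: 0.0 for f in mir_ids}
    batch = config.batch_shift * rng.standard_normal(config.n_cohorts_mirna)
    cohorts = [
        _simulate_cohort(
            mir_ids,
            biotypes,
            no_modules,
            no_loadings,
            truth.de_table,
            config,
            rng,
            f"cohortM{d + 1}",
            batch[d],
            0,
        )
        for d in range(config.n_cohorts_mirna)
    ]
    return cohorts, truth


_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_transcripts(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, str], dict[str, str], dict[str, str], GroundTruth]:
    """Generate lncRNA transcripts, mRNA 3'-UTRs and mature miRNAs.

    Background sequence is i.i.d. uniform over {A,C,G,U}.  The planted
    hub lncRNA and the planted mRNA 3'-UTR each receive
    ``n_planted_sites`` non-overlapping 8mer sites for the planted
    miRNA.  Each planted site sits at the 3' end of a longer stretch
    complementary to miRNA positions 2-16, so a duplex energy scan
    finds a stable hybrid there, as it would at a genuine sponge site.
    Site coordinates (of the 8mer proper) are appended to the truth.

    Returns (lncrna_fasta, utr_fasta, mirna_fasta, truth).
    """
    if not truth.planted_mirna:
        raise ConfigurationError("truth lacks a planted miRNA id")
    rng = np.random.default_rng([config.rng_seed, 7919])
    _, lnc_ids, mir_ids = _feature_ids(config)

    mirnas = {m: _random_rna(rng, config.mirna_len) for m in mir_ids}
    planted_mir = mirnas[truth.planted_mirna]

    # extended complementary insert: revcomp of miRNA nt 2..16 followed
    # by the A anchor opposite position 1; its last 8 nt are the 8mer site
    pair_span = min(16, config.mirna_len)
    insert = reverse_complement(planted_mir[1:pair_span]) + "A"
    site_len = 8

    def plant(seq: str, transcript_id: str, n_sites: int | None = None) -> str:
        n_sites = config.n_planted_sites if n_sites is None else n_sites
        if n_sites == 0:
            return seq
        needed = n_sites * (len(insert) + 4)
        if len(seq) < needed:
            raise ConfigurationError(
                f"transcript_len={len(seq)} too short for "
                f"{n_sites} planted sites of {len(insert)} nt"
            )
        seq_list = list(seq)
        stride = len(seq) // n_sites
        for k in range(n_sites):
            start = k * stride + (stride - len(insert)) // 2
            seq_list[start : start + len(insert)] = list(insert)
            site_start = start + len(insert) - site_len
            truth.planted_sites.append(
                (transcript_id, site_start, site_start + site_len, "8mer")
            )
        return "".join(seq_list)

    lncrnas: dict[str, str] = {}
    for lnc in lnc_ids:
        seq = _random_rna(rng, config.transcript_len)
        if lnc == truth.planted_hub_lncrna:
            seq = plant(seq, lnc)
        elif lnc in truth.decoy_lncrnas:
            seq = plant(seq, lnc, n_sites=1)
        lncrnas[lnc] = seq

    mrna_ids = sorted({truth.planted_mrna} | set(truth.module_assignment) - set(lnc_ids))
    utrs: dict[str, str] = {}
    for mrna in mrna_ids:
        if not mrna.startswith("mRNA:"):
            continue
        seq = _random_rna(rng, config.transcript_len)
        if mrna == truth.planted_mrna:
            seq = plant(seq, mrna)
        utrs[mrna] = seq
    return lncrnas, utrs, mirnas, truth


def simulate_all(config: SimulationConfig):
    """Run all three generators consistently from one config.

    Returns (expression cohorts, mirna cohorts, lncrna_fasta,
    utr_fasta, mirna_fasta, truth).
    """
    cohorts, truth = simulate_expression_cohorts(config)
    mir_cohorts, truth = simulate_mirna_cohorts(config, truth)
    lnc_fa, utr_fa, mir_fa, truth = simulate_transcripts(config, truth)
    return cohorts, mir_cohorts, lnc_fa, utr_fa, mir_fa, truth
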