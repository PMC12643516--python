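# Methods

This note records the models, parameter choices, numerical decisions
and known limitations behind ceRNAscout.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic study conditions

The generator (`cernascout.simulate`) produces the data every
downstream stage is verified against.  Each mRNA+lncRNA cohort is
drawn from a Gaussian latent-factor model

    x_gs = mu_g + lambda_g * f_{m(g),s} + delta_g * c_s + b_d + eps_gs

with one standard-normal factor per coexpression module (shared by a
module's members within a sample, independent across samples and
cohorts), case indicator c_s, per-cohort offset b_d ~ N(0, 0.5²), and
noise eps ~ N(0, sigma²).  Factors are centered within each group, so
module membership is exactly orthogonal to case status and, at
sigma = 0, the realized case-minus-control mean equals delta_g exactly
for every feature.

Reference conditions (the defaults): 2000 mRNAs + 100 lncRNAs in 8
cohorts and 50 miRNAs in 2 cohorts, 50 + 50 samples each; 5 modules of
30–60 features with loading 0.8; planted hub lncRNA with loading 1.2
and delta = +1; planted miRNA delta = −1; planted mRNA delta = +1 in
the hub's module; 10% of features differentially expressed.  Values
are on a log2-like scale around a baseline of 7.

Two generator choices deserve justification:

* **Heterogeneous background effects.**  Non-planted DE features draw
  their magnitude from U(0.3, 0.8) × delta, so the planted triad
  members are the headline (largest-effect) genes of the study.  This
  mirrors the discovery setting the package targets, where the triad
  mRNA is the top gene of the meta-analysis; with homogeneous effects
  the "top target of the top miRNA" would be an ill-posed notion and
  no method could rank the planted triple first.
* **Decoy sponge partners.**  Three additional differentially
  expressed lncRNAs each carry one planted site for the planted miRNA.
  A ceRNA hub miRNA characteristically has several predicted lncRNA
  partners, and its network degree — one of the three triad-ranking
  criteria — is only meaningful if the generator reproduces that.

Planted sites are 8mers (reverse complement of miRNA positions 2–8
plus the A anchor) embedded at the 3' end of a stretch complementary
to miRNA positions 2–16, so the duplex scan finds an extended, strongly
stabilizing hybrid (typically −25 to −40 kcal/mol) at the recorded
coordinates.  Background sequence is i.i.d. uniform RNA; chance 8mers
occur at rate ~(1/4)^8 per position.

What the generator does **not** emulate: probe-level microarray
artifacts, platform-specific intensity distributions, heavy-tailed
expression noise, correlated DE structure beyond the latent factors,
and genome-derived sequence composition.  Passing tests therefore
demonstrate that each stage recovers the structure it is designed to
detect under its stated model, not that real cohorts satisfy that
model.

## Meta-analysis

Per-cohort normalization approximates variance-stabilized microarray
preprocessing with log2(x+1) (raw inputs only) followed by quantile
normalization; the downstream statistics are rank/variance-driven and
no published variance-stabilization parameters exist to reproduce.
Batch adjustment is a parametric empirical-Bayes location/scale model:
features are standardized under a batch + group design (the group
effect is part of the design and survives adjustment), per-batch
additive effects get a normal prior and multiplicative effects an
inverse-gamma prior, both moment-matched across features and applied
in one shrinkage step (non-iterative).  A batch coinciding 1:1 with
the condition is rejected as confounded.

The moderated t fits the prior (d0, s0²) by matching the mean and
variance of log s²_g through digamma/trigamma moment equations, with a
Newton trigamma inverse.  d0 = infinity (homogeneous variances) is a
valid outcome and uses the normal reference distribution; a failed fit
(e.g. a single feature) falls back to the ordinary pooled t with a
logged warning.

Cross-cohort combination reports both T_comb = sum of per-cohort
moderated t (plain, unweighted sum; direction = its sign) and Fisher's
X² = −2 Σ ln p with the upper chi-square tail at 2k df.  Zero p-values
are clamped to 1e-300 before the log.  Which per-cohort p enters the
combination is a per-panel choice: raw p for mRNA panels, BH-adjusted
p for miRNA and lncRNA panels.  Features must be measured in ≥ 2
cohorts (≥ 1 when only one cohort is supplied).  No |logFC| cutoff is
applied by default.  Probe-to-gene collapse, when needed, keeps the
probe of maximal mean expression.

## Coexpression

The network is unsigned (a_ij = |cor|^beta, Pearson,
pairwise-complete on masked values, zero diagonal).  The soft
threshold is either fixed (default beta = 6) or chosen as the smallest
candidate whose signed scale-free fit R² (log-log regression of the
10-bin connectivity histogram) reaches 0.80, falling back to the
best-fitting candidate with a warning.

Module detection cuts the average-linkage dendrogram of 1 − TOM at a
**static height placed on the merge-height range**:
h = h_min + q(deep_split) · (h_max − h_min), with q = {0: 0.97,
1: 0.96, 2: 0.95, 3: 0.93, 4: 0.90}.  Placing the cut on the range
rather than at a fixed fraction of the maximum height is deliberate:
for weak latent-factor signal the 1 − TOM merge heights compress into
a narrow band just below 1, where any fixed absolute cut lands below
every merge and shatters the tree.  The range-based cut reduces to a
fraction-of-maximum cut when the first merges are near 0 (strong block
structure) and stays monotone in deep_split.  The q table was
calibrated once on the reference synthetic conditions and frozen.
Clusters below min_module_size (default 30) fall into module 0;
modules are numbered by decreasing size.

Sample-outlier removal cuts the Euclidean average-linkage sample tree
at cut_height_frac × max merge height (default 0.75) and keeps the
largest cluster — but only when that cluster holds ≥ 75% of the
samples; otherwise the split is taken to be biological (e.g. case vs
control) and nothing is removed.  In `run-all`, coexpression operates
on the pooled (sample-concatenated, post-normalization) matrix of all
lncRNA-measuring cohorts: pooling drives the background-correlation
noise floor (|r| ~ n^(-1/2)) far below the module signal, which a
single 100-sample cohort cannot achieve at the reference loading and
noise.

Eigengenes are the first principal component of the z-scored member
matrix, unit-variance, sign-oriented to non-negative mean member
correlation.  Hub selection takes the lncRNA of maximal intramodular
connectivity per module; ties break by adjacency-edge count at the
edge cutoff (default 0.1), then by smaller meta-analysis adjusted p.

## Sponge network and triads

Seed matching is exact string matching of the canonical classes, and
is strictly Watson–Crick; each target window is reported once under
its most specific class.  Coordinates are 0-based half-open
everywhere in code.

Duplex energies come from a dynamic program over intermolecular
pairing only — no intramolecular structure, no dangling ends, no
initiation term (a window with no stabilizing pairing scores exactly
0).  Pairs may be Watson–Crick or G:U.  Stacked pairs score the
published nearest-neighbor stacking free energies; bulges cost
3.8 + 0.5·(n−1) kcal/mol and internal loops 2.0 + 0.5·(a+b−2), with no
loop-size cap.  The parameter table ships as a versioned data file
(`data/nn_params.yaml`).  During development the model was sanity-
checked against a full-featured hybridization tool on random 38 × 22-nt
windows (medians within ~1 kcal/mol); absolute energies are therefore
comparable to, but not duplicates of, tool-specific values.  The DP is
exactly equivalent to exhaustive structure enumeration under the same
cost model (verified to 1e-9 for all pairs ≤ 8 nt).

Edges require ≥ 1 site of class ≥ 7mer-m8 (configurable) and best MFE
over site ± 15 nt windows ≤ −20 kcal/mol (configurable).  Both
candidate lists are restricted to meta-significant features in the
pipeline.  Admission is monotone in both knobs.  miRNA ranking is by
degree, then best MFE, then id.  Triad candidates must be
direction-consistent (lncRNA up, miRNA down, mRNA up — or the global
mirror, which is labelled); the composite rank is the mean of the
ranks of hub kWithin, miRNA degree, and mRNA |T_comb|, with
deterministic id tie-breaks.

ORF/coding-potential triage enumerates all forward-strand AUG→stop
ORFs (min 75 nt by default) and computes the Fickett TESTCODE score
from the published position/composition lookup tables
(`data/fickett_tables.yaml`); calls use the published bands (< 0.74
noncoding-like, > 0.95 coding-like, otherwise borderline).

## Enrichment

ORA uses the hypergeometric upper tail with the universe defaulting to
all features measured in the meta-analysis (not the genome).  GSEA
uses the weighted running sum (weight exponent 1) with a
**gene-label** permutation null — dataset-free and cheap, a documented
divergence from phenotype permutation; consequences: inter-gene
correlation is not preserved under the null, so real-data p-values are
anti-conservative in correlated sets.  The nominal p is the two-sided
permutation tail (|null ES| ≥ |ES|) with the +1 correction, so it is
never 0 and is uniform under the null; NES divides ES by the mean
|null ES| of matching sign.

## Determinism and numerics

All randomness flows from integer seeds through `numpy.random.Generator`;
the miRNA-cohort and transcript streams are derived from the same seed
with distinct fixed salts.  Repeated runs with one seed are
byte-identical, including all written artifacts (the run log is the
only file carrying incidental content).  Ties: quantile normalization
averages tied ranks; hub selection, miRNA ranking and triad ordering
end in lexicographic id comparisons; the duplex DP keeps the first of
equal-energy structures in scan order.  Degenerate inputs (single
feature, single column, empty networks, module-less partitions,
hub-less modules, sets covering the whole ranked list) return defined
results or clear errors rather than propagating NaN.

## Problem sizes used in verification

The acceptance script and test suite run the full pipeline at the
reference conditions over 20 seeds, null calibrations at 20 × 500 (and
20 × 300 × 2 cohorts) features, GSEA null uniformity on 100 sets × 500
permutations, module recovery on the 90-feature two-block design over
10 seeds, and oracle batteries of 100–1800 cases per kernel.  These
sizes keep a complete verification run at roughly three minutes on one
CPU while leaving every estimate's Monte-Carlo error well inside the
asserted bands.

## Known limitations

* Combined T as a plain sum of moderated t is one convention among
  several; no weighting by cohort size is applied.
* The static range-based tree cut is a fully specified stand-in for
  dynamic hybrid tree cutting; on real data it will typically find
  fewer, coarser modules.
* Duplex energies ignore site accessibility, intramolecular structure
  and dangling-end stabilization.
* Seed matching does not model 3'-compensatory or bulged sites beyond
  what the duplex energy window captures.
* The coding-potential triage is the composition/position statistic
  only; it is not a trained classifier.
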