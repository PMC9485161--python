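# Methods

This note documents the models, conventions and numerical choices behind
`ribohet`, and what the synthetic-data generators do and do not emulate.

## Relative quantification of ribosomal proteins

The proteomic input is TMT-based relative quantification: for each peptide
of each ribosomal protein (RP), a log2 ratio of a differentiated-cell
channel against the hESC reference channel. Protein-level values are the
**median** of the peptide log2 ratios per (protein, sample); the mean is
available as a config option. The median was chosen because the upstream
search engine's protein-roll-up algorithm is not specified in enough detail
to reproduce, and the median is robust and reproducible. Missing peptides
or proteins are simply absent — no imputation anywhere.

Each sample is then normalized by subtracting, in log2 space, the median
value over the observed RPs of each subunit (40S or 60S). This removes any
per-sample, per-subunit multiplicative offset — notably TMT
labeling-efficiency differences and differences in total subunit amounts —
and leaves the per-subunit median at exactly zero (asserted to 1e-12). The
operation is idempotent and equivalent to dividing by the median linear
ratio. mRNA abundance joins the same schema by dividing each RP's TPM by
its mean TPM over hESC replicates, taking log2, and applying the same
subunit-median step; RPs with zero reference-mean TPM are dropped with a
warning.

The bundled annotation covers the 80 core human RPs (33 small-subunit
including RACK1; 47 large-subunit) plus the eL22L paralog row, keyed by
gene symbol with universal nomenclature aliases.

## Heterogeneity classification

An RP is *heterogeneous* when a one-way fixed-effects ANOVA of its
replicate-level normalized log2 abundances across the seven differentiated
cell types gives P < 0.05. The hESC reference is the ratio denominator,
not a group, so it is excluded by default. No multiple-testing correction
is applied to the 80 ANOVA P values (Benjamini–Hochberg is available as an
option). Degenerate conventions: all values identical → P = 1; zero
within-group variance with non-zero between-group variance → P = 0.

The published screen additionally requires magnitude: a heterogeneous RP is
*strong* when its per-cell-type median changes by at least 10% on the
linear ratio scale (|2^median − 1| ≥ 0.10) in at least two differentiated
cell types. The 10% rule is evaluated on the linear scale because the
ratio, not its log, is the stated quantity; an optional stricter variant
additionally requires a per-cell-type one-sample t test at P < 0.05.

Progressive lineage changes are scored by ordinary least squares of
replicate-level log2 values on the ordinal mesoderm stage index (anterior
primitive streak = 1 … sclerotome = 4); the hESC reference can optionally
enter as stage 0 at value 0, off by default since the published design does
not state it. Cross-compartment concordance is the Spearman correlation of
per-cell-type medians (7 points when complete, ≥4 required), with
average-rank ties.

## Solvent exposure

SASA is computed with the Shrake–Rupley method: `n_points` (default 960)
test points on a deterministic spherical Fibonacci lattice are placed on
each atom's probe-inflated sphere (probe 1.4 Å); a point is accessible iff
it lies outside every other atom's inflated sphere; neighbor candidates
come from a spatial hash grid with cell size 2·(r_max + probe). Van der
Waals radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; unknown elements
require explicit overrides. Waters are excluded and only the first-listed
alternate conformer is kept.

A chain's *exposed fraction* is its SASA inside the full assembly divided
by its SASA in isolation — the ratio form of "total surface minus all
interface area". Heteroatoms and unmapped chains (rRNA, factors) act as
occluders but are excluded from the per-RP results. Enrichment of exposure
among heterogeneous RPs uses the two-sided Mann–Whitney test.

Accuracy at 960 points: an isolated sphere agrees with 4π(r+probe)² to
better than 0.5%, and the two-sphere overlap agrees with the
spherical-cap closed form to better than 1%. Because each atom's
accessible fraction is quantised in steps of 1/n_points, rigid-motion
invariance of a small cluster's total SASA holds to roughly one lattice
point per atom (~0.5% at 960 points, tightening as the lattice refines);
per-chain values converge to <0.5% when the point count doubles.

## Ribosome profiling and translation efficiency

Coordinates are 0-based and half-open throughout. The A-site offset for
each footprint length L is calibrated from reads whose 5′ ends fall within
30 nt upstream of an annotated start codon: offset(L) is the modal
(cds_start − 5′ end) distance plus 4 nt, ties broken toward the smaller
distance, and lengths with fewer than 200 supporting reads are dropped.
Footprints are counted at their A site (5′ + offset) and must fall within
the CDS trimmed of its first 15 and last 5 codons, i.e. in
[cds_start + 45, cds_end − 15); RNA-seq reads count anywhere on the
transcript. Genes are retained when cpm > 0.75 (computed on raw counts) in
at least three footprint libraries, and the retained set is applied to both
assays; the filter precedes normalization.

Between-library scaling uses the trimmed mean of M-values (TMM): the
reference library is the one whose 75th-percentile count fraction is
closest to the mean of those fractions; per library, M and A values over
genes positive in both libraries are doubly trimmed (30% of genes from each
tail of M, 5% from each tail of A, the edgeR convention) and averaged with
inverse asymptotic-variance weights; factors are rescaled to geometric
mean 1. Fewer than 20 surviving genes triggers an untrimmed fallback with a
warning.

TE inference is intentionally simple and transparent rather than a
moderated linear-model stack: per gene and replicate, TE is log2 footprint
cpm minus log2 RNA cpm (TMM-scaled totals, +0.5 pseudocount), paired by
replicate when the designs match; the genotype contrast is a two-sided
Welch t, BH-corrected across genes. Per-assay contrasts are tested the same
way, and genes are classed at per-assay FDR < 0.1 as RPF-only, RNA-only,
both or neither. 5′UTR GC content of down-translated (RPF-significant,
negative fold change) versus unchanged genes is compared by Mann–Whitney.

## qPCR arithmetic

All conversions assume amplification efficiency 2 (per-target efficiencies
are a config hook). "Undetermined" reactions carry Ct = 40 as a
conservative overestimate; they are tolerated for targets but are an error
for any normalizer (reference gene, spike-in, control transcript).
Relative expression is 2^−ΔCt against the reference gene; sucrose-gradient
distributions first normalize each fraction's target Ct to the luciferase
spike-in, linearize, and normalize to the summed abundance over the five
fractions (shares sum to 1 by construction); ribosome-IP association is the
control-normalized elution/input ratio.

## Statistical kernel

Standard tests are routed through scipy/statsmodels with explicit
conventions: Welch's t with Satterthwaite df (zero-variance groups decided
by the means); exact Mann–Whitney when min(n) ≤ 8 without ties, otherwise
the normal approximation with tie and continuity corrections; Fisher's
exact summing hypergeometric probabilities ≤ observed; BH step-up with
enforced monotonicity. Watson's two-sample U² for circular data is
implemented directly: the statistic is computed over the pooled sorted
angles with tied values sharing a single CDF step, and inference is by
random permutation of group labels with the add-one estimator
(b+1)/(n_perm+1), default n_perm = 9999; asymptotic critical values are
reported alongside. Permutation makes the tie convention immaterial for
validity, and the statistic is origin-invariant.

## Synthetic data: what it emulates and what it does not

Generators share one seed; generator *g* draws from
`default_rng([seed, k_g])` with a fixed per-generator stream key, so runs
are byte-identical under a fixed seed and each generator is independent of
the others.

- **TMT**: peptide log2 ratio = planted effect(rp, cell type) + a
  per-(sample, subunit) labeling-efficiency offset + Normal(0, 0.1) peptide
  noise; ~Poisson(8) peptides per RP; 7 differentiated cell types × 6
  replicates; optional missing-at-random peptides and whole-RP dropout. The
  per-subunit offset is constructed so subunit-median normalization removes
  it exactly — zero-noise data invert bit-for-bit. Planted screens use
  0.32 log2 (25%) effects in ≥2 cell types, a fraction of them progressive
  along the mesoderm lineage. Defaults mirror the study's design (replicate
  counts, noise comparable to the reported ~0.15 inter-peptide SD). Not
  emulated: correlated peptide effects, batch structure, compartments
  driven by a shared biological state.
- **Assemblies**: sphere-cluster chains in disjoint, fully enclosed, or
  two-sphere-overlap geometry, with exposed fractions known in closed form
  (spherical caps). Real chain shapes, packing and rRNA are not emulated —
  the toys validate the engine, not ribosome biology.
- **Reads**: 300 transcripts (100 nt 5′UTR, 300–1200 nt CDS), footprint 5′
  ends at (A-site codon − offset(L)) inside the trimmed window plus an
  initiation pile-up at distance offset(L)−4 upstream of the start; per-gene
  expression is lognormal (σ = 0.75) and 120k footprint/RNA reads per
  library give several hundred reads per gene, so Poisson noise is small
  against the planted one-log2 TE effects (3v3 genotype design, 50
  down-regulated genes, high-GC 5′UTRs on the down set). Truth counts are
  the realized placed reads, so zero-jitter data reproduce the count matrix
  exactly. Not emulated: rRNA contamination, UMI duplicates, codon-level
  pausing, uneven coverage.
- **Ct tables / angles**: Ct = baseline − log2(abundance) + noise, clamped
  to (0, 40] with "Undetermined" beyond; angles are von Mises (κ = 0 is
  uniform), with group sizes 151/127 matching the validation experiment's
  scale.

Passing recovery tests therefore demonstrates correctness of the
computational chain under its own assumptions — unbiased recovery of
planted effects at realistic noise — not robustness to every artefact of
real instruments.

## Problem sizes used by the test and acceptance runs

Recovery simulations run at desk scale, chosen as the smallest sizes at
which the Monte-Carlo error is far below the asserted margins: 500 seeds
for the proteomic screen (recall/false-flag rates, ANOVA null
calibration), 40 seeds for the TE recovery (each a full
generate→calibrate→count→filter→normalize→test chain over 12 libraries),
2000 null replicates for Watson-U² calibration at 99 permutations, and the
published validation scale (151/127 angles) for its power check. The
acceptance script re-runs the same computations at 300/25/500/100
replicates respectively.

## Known limitations

- The TE test is a replicate-level Welch t, not an empirical-Bayes
  moderated model; with only 2–3 replicates per group its power depends on
  read depth, and no surrogate-variable/batch correction is applied.
- The exposed-fraction definition (in-complex / isolated SASA) matches
  "surface minus interfaces" only when interfaces are disjoint; a
  per-interface decomposition is out of scope.
- Exact reproduction of the published screen counts (31/14, the
  per-RP correlation values, 77+1 quantified RPs) requires the deposited
  replicate-level tables, which are not bundled; the screens themselves are
  validated against planted synthetic truth.
- The Mann–Whitney asymptotic path is used for any tied data regardless of
  sample size; for heavily tied small samples an exact tie-aware
  enumeration is not provided.
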