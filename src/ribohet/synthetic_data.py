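"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data model of the study: TMT peptide log2 ratios
of 80 ribosomal proteins across seven differentiated cell types against an
hESC reference (with per-sample, per-subunit labeling-efficiency offsets
that subunit-median normalization provably removes); toy sphere assemblies
whose solvent-accessible surface areas have closed forms; ribosome-protected
footprints with planted per-length A-site offsets and translation-efficiency
changes; qPCR Ct tables with known fold changes; and von Mises angle
samples for the circular statistics.

All randomness flows from ``SimConfig.seed`` through a fixed splitting
scheme: generator *g* draws from ``numpy.random.default_rng([seed, k_g])``
with a distinct stream key ``k_g`` per generator, so each generator is
individually reproducible and independent of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rp_quant import load_annotation
from .structure_exposure import AtomSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "planted_effect_profiles",
    "generate_tmt",
    "generate_assembly",
    "generate_reads",
    "generate_ct",
    "generate_angles",
]

#: default cell types: mesoderm lineage stages, then endoderm lineage stages
DEFAULT_CELL_TYPES = (
    "anterior_primitive_streak", "paraxial_mesoderm", "early_somite",
    "sclerotome", "anterior_most_primitive_streak", "definitive_endoderm",
    "mid_hindgut",
)
MESODERM_STAGES = DEFAULT_CELL_TYPES[:4]
REFERENCE_CELL_TYPE = "hESC"

# fixed stream keys of the seed-splitting scheme (never reorder)
_STREAM_TMT, _STREAM_ASSEMBLY, _STREAM_READS, _STREAM_CT, _STREAM_ANGLES = range(5)


@dataclass
class SimConfig:
    """Parameters of all synthetic datasets; one seed drives everything."""

    seed: int = 0
    # --- TMT / proteomics ---
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_replicates: int = 6
    peptides_per_rp: float = 8.0
    peptide_noise_sd: float = 0.1
    label_efficiency_sd: float = 0.1
    missing_rate: float = 0.0
    dropped_rps: tuple[str, ...] = ()
    effect_profiles: dict | None = None
    # --- toy assembly ---
    assembly_geometry: str = "two_sphere"  # disjoint | enclosed | two_sphere
    sphere_radius: float = 2.0
    sphere_distance: float = 3.0
    probe_radius: float = 1.4
    # --- ribosome profiling ---
    n_genes: int = 300
    n_rpf_reads: int = 120_000
    n_rna_reads: int = 120_000
    expression_sigma: float = 0.75
    n_ribo_replicates: int = 3
    genotypes: tuple[str, str] = ("WT", "LOF")
    true_offsets: dict = field(default_factory=lambda: {
        28: 16, 29: 16, 30: 17, 31: 17, 32: 18, 33: 18, 34: 19})
    read_jitter: float = 0.0
    init_fraction: float = 0.15
    delta_te: dict | None = None
    n_te_down: int = 50
    te_effect_log2: float = -1.0
    rna_read_length: int = 50
    utr5_gc_down: float = 0.7
    utr5_gc_other: float = 0.5
    # --- qPCR ---
    ct_baseline: float = 20.0
    ct_sd: float = 0.0
    qpcr_fold_changes: dict = field(default_factory=lambda: {
        "target_up": 2.0, "target_down": 0.125})
    gradient_shares: tuple[float, ...] = (1 / 3, 1 / 6, 1 / 6, 1 / 6, 1 / 6)
    ip_enrichment_true: float = 1.5
    # --- angles ---
    angle_mu: tuple[float, float] = (0.0, 0.0)
    angle_kappa: tuple[float, float] = (2.0, 2.0)
    n_angles: tuple[int, int] = (151, 127)

    def __post_init__(self) -> None:
        if self.n_replicates <= 0 or self.peptides_per_rp <= 0:
            raise ValueError("replicate and peptide counts must be positive")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if min(self.peptide_noise_sd, self.label_efficiency_sd,
               self.ct_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for length, off in self.true_offsets.items():
            if off >= length:
                raise ValueError(
                    f"offset {off} must be smaller than read length {length}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimTruth:
    """Planted parameters asserted against by the recovery tests."""

    effects: pd.DataFrame | None = None           # rp x cell type, log2
    heterogeneous_rps: set = field(default_factory=set)
    exposed_fractions: dict = field(default_factory=dict)
    offsets: dict = field(default_factory=dict)
    counts: pd.DataFrame | None = None            # gene x library placed reads
    delta_te: dict = field(default_factory=dict)
    qpcr_fold_changes: dict = field(default_factory=dict)
    gradient_shares: dict = field(default_factory=dict)
    ip_enrichment: float | None = None
    angle_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# TMT proteomics
# ---------------------------------------------------------------------------

def planted_effect_profiles(rp_ids: list[str], n_heterogeneous: int = 14,
                            magnitude: float = 0.32,
                            n_affected_cell_types: int = 2,
                            cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
                            progressive_fraction: float = 0.3,
                            seed: int = 0) -> dict[str, dict[str, float]]:
    """Plant per-cell-type log2 effects for a subset of RPs.

    A fraction of planted RPs get a progressive profile along the mesoderm
    lineage (linear in stage, peak |effect| = ``magnitude``); the rest get
    ``magnitude`` (alternating sign) in ``n_affected_cell_types`` randomly
    chosen cell types.  Every planted RP has |effect| >= magnitude in at
    least ``n_affected_cell_types`` cell types.
    """
    rng = np.random.default_rng([seed, 97])
    chosen = rng.choice(len(rp_ids), size=n_heterogeneous, replace=False)
    profiles: dict[str, dict[str, float]] = {}
    n_prog = int(round(progressive_fraction * n_heterogeneous))
    for j, idx in enumerate(chosen):
        rp = rp_ids[idx]
        sign = -1.0 if j % 2 else 1.0
        if j < n_prog:
            stages = [ct for ct in MESODERM_STAGES if ct in cell_types]
            ramp = np.linspace(magnitude, 2.0 * magnitude, len(stages))
            profiles[rp] = {ct: sign * ramp[i] for i, ct in enumerate(stages)}
        else:
            picks = rng.choice(len(cell_types), size=n_affected_cell_types,
                               replace=False)
            profiles[rp] = {cell_types[k]: sign * magnitude for k in picks}
    return profiles


def generate_tmt(config: SimConfig, compartment: str = "polysome",
                 ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Peptide-level TMT log2 ratios with planted effects.

    Each peptide log2 ratio = effect(rp, cell type) + labeling offset
    (per sample, per subunit) + Normal(0, peptide_noise_sd).  Peptides are
    unobserved independently at ``missing_rate``; RPs listed in
    ``dropped_rps`` are absent entirely (whole-protein dropout).
    """
    rng = config.rng(_STREAM_TMT)
    ann = load_annotation(core_only=True)
    ann = ann[~ann["rp_id"].isin(config.dropped_rps)].reset_index(drop=True)
    rp_ids = ann["rp_id"].to_list()
    subunit = ann["subunit"].to_numpy()
    n_rp = len(rp_ids)

    profiles = config.effect_profiles or {}
    effects = pd.DataFrame(0.0, index=rp_ids, columns=list(config.cell_types))
    for rp, per_ct in profiles.items():
        for ct, val in per_ct.items():
            effects.loc[rp, ct] = val

    n_pep = np.maximum(1, rng.poisson(config.peptides_per_rp - 1,
                                      size=n_rp) + 1)
    samples = [(ct, r) for ct in config.cell_types
               for r in range(1, config.n_replicates + 1)]
    n_samples = len(samples)
    # labeling-efficiency offset: one value per (sample, subunit)
    label_off = rng.normal(0.0, config.label_efficiency_sd,
                           size=(n_samples, 2))
    subunit_col = (subunit == "60S").astype(int)

    rows = []
    total_pep = int(n_pep.sum())
    noise = rng.normal(0.0, config.peptide_noise_sd,
                       size=(n_samples, total_pep))
    miss = (rng.random((n_samples, total_pep)) < config.missing_rate
            if config.missing_rate > 0 else
            np.zeros((n_samples, total_pep), dtype=bool))
    pep_rp = np.repeat(np.arange(n_rp), n_pep)
    pep_num = np.concatenate([np.arange(1, k + 1) for k in n_pep])
    rp_arr = np.asarray(rp_ids, dtype=object)[pep_rp]
    pep_names = np.array([f"{rp}_pep{p}" for rp, p in zip(rp_arr, pep_num)],
                         dtype=object)
    eff_mat = effects.to_numpy()  # n_rp x n_ct
    for s, (ct, rep) in enumerate(samples):
        ct_idx = list(config.cell_types).index(ct)
        vals = (eff_mat[pep_rp, ct_idx]
                + label_off[s, subunit_col[pep_rp]]
                + noise[s])
        keep = ~miss[s]
        rows.append(pd.DataFrame({
            "sample_id": f"{ct}_rep{rep}", "compartment": compartment,
            "cell_type": ct, "replicate": rep,
            "rp_id": rp_arr[keep],
            "peptide_id": pep_names[keep],
            "log2_ratio": vals[keep],
        }))
    table = pd.concat(rows, ignore_index=True)
    meta = pd.DataFrame([{"sample_id": f"{ct}_rep{r}", "compartment": compartment,
                          "cell_type": ct, "replicate": r}
                         for ct, r in samples])
    truth = SimTruth(effects=effects, heterogeneous_rps=set(profiles))
    return table, meta, truth


# ---------------------------------------------------------------------------
# toy assemblies with closed-form SASA
# ---------------------------------------------------------------------------

def _atomset(chains: list[tuple[str, np.ndarray, float]]) -> AtomSet:
    chain_id, xyz, radius = [], [], []
    for cid, coords, r in chains:
        coords = np.atleast_2d(coords)
        chain_id.extend([cid] * len(coords))
        xyz.append(coords)
        radius.extend([r] * len(coords))
    xyz = np.vstack(xyz)
    n = len(chain_id)
    return AtomSet(np.array(chain_id, dtype=object),
                   np.array(["SPH"] * n, dtype=object),
                   np.arange(1, n + 1),
                   np.array(["C"] * n, dtype=object),
                   xyz, np.array(radius))


def two_sphere_exposed_fraction(r: float, probe: float, d: float) -> float:
    """Closed-form exposed fraction for two equal spheres at center distance d.

    Each probe-inflated sphere of radius R = r + probe loses a spherical cap
    of area 2*pi*R*h with h = R - d/2; the exposed fraction is the retained
    area over the full sphere: 1 - h / (2R).
    """
    R = r + probe
    if d >= 2 * R:
        return 1.0
    h = R - d / 2.0
    return 1.0 - h / (2.0 * R)


def generate_assembly(config: SimConfig) -> tuple[AtomSet, SimTruth]:
    """Toy multi-chain sphere assembly with analytically known exposure."""
    r = config.sphere_radius
    d = config.sphere_distance
    geom = config.assembly_geometry
    if geom == "disjoint":
        atoms = _atomset([("A", np.array([0.0, 0.0, 0.0]), r),
                          ("B", np.array([100.0, 0.0, 0.0]), r)])
        truth = {"A": 1.0, "B": 1.0}
    elif geom == "two_sphere":
        if d <= 0:
            raise ValueError("overlapping identical centers rejected")
        atoms = _atomset([("A", np.array([0.0, 0.0, 0.0]), r),
                          ("B", np.array([d, 0.0, 0.0]), r)])
        f = two_sphere_exposed_fraction(r, config.probe_radius, d)
        truth = {"A": f, "B": f}
    elif geom == "enclosed":
        # single-atom chain fully occluded by a shell of fat atoms
        shell_dirs = _fibonacci_dirs(64)
        atoms = _atomset([("A", np.array([0.0, 0.0, 0.0]), 1.5),
                          ("S", 4.0 * shell_dirs, 2.5)])
        truth = {"A": 0.0}
    else:
        raise ValueError(f"unknown assembly geometry {geom!r}")
    return atoms, SimTruth(exposed_fractions=truth)


def _fibonacci_dirs(n: int) -> np.ndarray:
    from .structure_exposure import fibonacci_sphere
    return fibonacci_sphere(n)


# ---------------------------------------------------------------------------
# ribosome profiling reads
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


def generate_reads(config: SimConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Footprint and RNA reads in transcript coordinates with planted truth.

    Returns (reads, transcript models, library metadata, truth).  Footprint
    5' ends are placed at (A-site position) - offset(L) for elongating
    ribosomes within the trimmed CDS window, plus an initiation pile-up at
    5' = cds_start - (offset(L) - 4) used for offset calibration.  Genes in
    the planted delta-TE set have their footprint (not RNA) expected counts
    scaled by 2^delta_te in mutant libraries.
    """
    rng = config.rng(_STREAM_READS)
    n_genes = config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    utr5_len = 100
    utr3_len = 60
    cds_codons = rng.integers(100, 400, size=n_genes)
    cds_len = 3 * cds_codons
    lengths = utr5_len + cds_len + utr3_len

    if config.delta_te is None:
        down = rng.choice(n_genes, size=config.n_te_down, replace=False)
        delta_te = {gene_ids[i]: config.te_effect_log2 for i in down}
    else:
        delta_te = dict(config.delta_te)

    gc = np.where(np.isin(gene_ids, list(delta_te)),
                  config.utr5_gc_down, config.utr5_gc_other)
    models = pd.DataFrame({
        "transcript_id": gene_ids,
        "transcript_length": lengths,
        "cds_start": utr5_len,
        "cds_end": utr5_len + cds_len,
        "utr5_sequence": [_random_seq(rng, utr5_len, g) for g in gc],
    })

    expr = rng.lognormal(mean=0.0, sigma=config.expression_sigma,
                         size=n_genes)
    expr /= expr.sum()
    te_scale = np.ones(n_genes)
    for g, dte in delta_te.items():
        te_scale[gene_ids.index(g)] = 2.0 ** dte

    offsets = dict(config.true_offsets)
    len_choices = np.array(sorted(offsets))
    libs = []
    for assay in ("RPF", "RNA"):
        for gt in config.genotypes:
            for rep in range(1, config.n_ribo_replicates + 1):
                libs.append({"library_id": f"{assay}_{gt}_rep{rep}",
                             "assay": assay, "genotype": gt,
                             "replicate": rep})
    lib_meta = pd.DataFrame(libs)

    mutant = config.genotypes[1]
    read_frames: list[pd.DataFrame] = []
    truth_counts = pd.DataFrame(0, index=gene_ids,
                                columns=lib_meta["library_id"])
    for _, lib in lib_meta.iterrows():
        is_rpf = lib["assay"] == "RPF"
        w = expr * (te_scale if (is_rpf and lib["genotype"] == mutant)
                    else 1.0)
        w = w / w.sum()
        n_reads = config.n_rpf_reads if is_rpf else config.n_rna_reads
        gene_of_read = rng.choice(n_genes, size=n_reads, p=w)
        if is_rpf:
            L = len_choices[rng.integers(0, len(len_choices), size=n_reads)]
            off = np.array([offsets[l] for l in len_choices])[
                np.searchsorted(len_choices, L)]
            is_init = rng.random(n_reads) < config.init_fraction
            # body reads: A-site at a codon start inside the trimmed window
            lo = models["cds_start"].to_numpy()[gene_of_read] + 45
            hi = models["cds_end"].to_numpy()[gene_of_read] - 15
            n_codon = (hi - lo) // 3
            a_site = lo + 3 * rng.integers(0, np.maximum(n_codon, 1))
            five_prime = a_site - off
            # initiation reads: modal 5'-to-start distance d = offset - 4
            init_fp = (models["cds_start"].to_numpy()[gene_of_read]
                       - (off - 4))
            five_prime = np.where(is_init, init_fp, five_prime)
            if config.read_jitter > 0:
                five_prime = five_prime + np.rint(
                    rng.normal(0, config.read_jitter, size=n_reads)).astype(int)
            five_prime = np.clip(five_prime, 0,
                                 lengths[gene_of_read] - L)
            counted = ~is_init
        else:
            L = np.full(n_reads, config.rna_read_length)
            five_prime = rng.integers(
                0, np.maximum(lengths[gene_of_read] - L + 1, 1))
            counted = np.ones(n_reads, dtype=bool)
        read_frames.append(pd.DataFrame({
            "transcript_id": np.asarray(gene_ids, dtype=object)[gene_of_read],
            "five_prime_pos": five_prime.astype(int),
            "length": L.astype(int),
            "library_id": lib["library_id"],
        }))
        binc = np.bincount(gene_of_read[counted], minlength=n_genes)
        truth_counts[lib["library_id"]] = binc
    reads = pd.concat(read_frames, ignore_index=True)
    truth = SimTruth(offsets=offsets, counts=truth_counts, delta_te=delta_te)
    return reads, models, lib_meta, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def _ct_from_abundance(rng: np.random.Generator, baseline: float,
                       abundance: float, sd: float) -> tuple[float, bool]:
    if abundance <= 0:
        return 40.0, True
    ct = baseline - np.log2(abundance) + (rng.normal(0, sd) if sd > 0 else 0.0)
    if ct > 40.0:
        return 40.0, True
    return float(max(ct, np.nextafter(0, 1))), False


def generate_ct(config: SimConfig, n_replicates: int = 3
                ) -> tuple[pd.DataFrame, SimTruth]:
    """Ct table covering the three qPCR analyses, with planted truth.

    Sections (distinguished by sample_id): expression replicates with
    targets at known fold changes relative to the reference gene; a sucrose
    gradient of 5 fractions with a constant-abundance spike-in; and an
    IP elution/input pair with a planted association ratio.
    """
    rng = config.rng(_STREAM_CT)
    rows = []

    def add(sample, target, abundance, fraction=None):
        ct, und = _ct_from_abundance(rng, config.ct_baseline, abundance,
                                     config.ct_sd)
        rows.append({"sample_id": sample, "target": target,
                     "fraction": fraction, "ct": ct, "undetermined": und})

    for rep in range(1, n_replicates + 1):
        sample = f"expr_rep{rep}"
        add(sample, "Nupl1", 1.0)
        for target, fold in config.qpcr_fold_changes.items():
            add(sample, target, fold)

    shares = np.asarray(config.gradient_shares, dtype=float)
    if shares.min() < 0 or abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("gradient shares must be non-negative and sum to 1")
    for f, share in enumerate(shares, start=1):
        add("gradient", "target_mrna", share, fraction=f)
        add("gradient", "luciferase_spike", 0.05, fraction=f)

    # IP: actin identical in both; target enriched in elution
    add("ip_input", "Actb", 1.0)
    add("ip_input", "target_mrna", 0.2)
    add("ip_elution", "Actb", 1.0)
    add("ip_elution", "target_mrna", 0.2 * config.ip_enrichment_true)

    table = pd.DataFrame(rows)
    truth = SimTruth(qpcr_fold_changes=dict(config.qpcr_fold_changes),
                     gradient_shares={"target_mrna": shares.tolist()},
                     ip_enrichment=config.ip_enrichment_true)
    return table, truth


# ---------------------------------------------------------------------------
# circular angle samples
# ---------------------------------------------------------------------------

def generate_angles(config: SimConfig) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Two angle samples (degrees in [0, 360)) from von Mises distributions.

    Concentration kappa = 0 gives the circular uniform distribution.
    """
    rng = config.rng(_STREAM_ANGLES)
    out = []
    for mu, kappa, n in zip(config.angle_mu, config.angle_kappa,
                            config.n_angles):
        if kappa < 0:
            raise ValueError("concentration must be >= 0")
        if kappa == 0:
            a = rng.uniform(0.0, 360.0, size=n)
        else:
            a = np.degrees(rng.vonmises(np.radians(mu), kappa, size=n)) % 360.0
        out.append(a)
    truth = SimTruth(angle_params={"mu": config.angle_mu,
                                   "kappa": config.angle_kappa,
                                   "n": config.n_angles})
    return out[0], out[1], truth
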