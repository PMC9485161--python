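"""Ribosome-profiling computational stage.

A-site offset calibration from read pile-ups at annotated start codons,
trimmed-CDS footprint counting, expression filtering, TMM between-library
normalization, and translation-efficiency (TE) change calls between two
genotypes.

Conventions (all coordinates 0-based, half-open):

* offset(L) = modal (cds_start - 5' end) over reads with 5' ends within 30
  nt upstream of a start codon, plus 4 nt; ties broken toward the smaller
  distance.
* A footprint is counted iff its A site (5' end + offset) lies in
  [cds_start + 45, cds_end - 15), i.e. the first 15 and last 5 codons of
  the CDS are removed; RNA-seq reads count anywhere on the transcript.
* Genes are retained when cpm > 0.75 (on raw counts) in at least three
  footprint libraries; the same gene set is applied to both assays.
* TE per gene and replicate is log2 footprint cpm minus log2 RNA cpm
  (TMM-normalized, +0.5 pseudocount); the genotype contrast on TE values
  is tested with Welch's t and BH-corrected across genes.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .stats_core import bh_adjust, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "calibrate_offsets",
    "count_cds",
    "filter_expressed",
    "tmm_normalize",
    "log_cpm",
    "te_change",
    "utr_gc_compare",
    "gc_fraction",
]


def calibrate_offsets(reads: pd.DataFrame, models: pd.DataFrame,
                      length_range: tuple[int, int] = (28, 34),
                      min_support: int = 200,
                      upstream_window: int = 30) -> pd.DataFrame:
    """Per-read-length A-site offsets from start-codon pile-ups.

    Returns a table (length, offset, support).  Lengths without
    ``min_support`` qualifying reads are dropped with a warning; if no
    length is calibratable this is an error.
    """
    mod = models.set_index("transcript_id")
    known = reads["transcript_id"].isin(mod.index)
    r = reads[known]
    cds_start = mod["cds_start"].reindex(r["transcript_id"]).to_numpy()
    d = cds_start - r["five_prime_pos"].to_numpy()
    lengths = r["length"].to_numpy()
    in_window = (d > 0) & (d <= upstream_window)
    rows = []
    for L in range(length_range[0], length_range[1] + 1):
        sel = in_window & (lengths == L)
        support = int(sel.sum())
        if support < min_support:
            logger.warning("read length %d: %d supporting reads "
                           "(< %d); length dropped", L, support, min_support)
            continue
        counts = Counter(d[sel].astype(int))
        top = max(counts.values())
        modal_d = min(k for k, v in counts.items() if v == top)  # tie: smaller
        rows.append({"length": L, "offset": modal_d + 4, "support": support})
    if not rows:
        raise ValueError("no read length could be calibrated")
    return pd.DataFrame(rows)


def count_cds(reads: pd.DataFrame, models: pd.DataFrame,
              offsets: pd.DataFrame | None, assay: str,
              trim_start_nt: int = 45, trim_end_nt: int = 15
              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene x library count matrix for one assay, plus a QC tally.

    RPF: the A site (5' end + offset(length)) must fall in
    [cds_start + trim_start_nt, cds_end - trim_end_nt); reads of
    uncalibrated lengths are dropped.  RNA: every read on a known
    transcript counts.  QC keys: counted, no_model, no_offset, outside.
    """
    if assay not in ("RPF", "RNA"):
        raise ValueError("assay must be 'RPF' or 'RNA'")
    mod = models.set_index("transcript_id")
    qc = {"counted": 0, "no_model": 0, "no_offset": 0, "outside": 0}
    known = reads["transcript_id"].isin(mod.index).to_numpy()
    qc["no_model"] = int((~known).sum())
    r = reads[known]
    if assay == "RPF":
        if offsets is None:
            raise ValueError("RPF counting requires an offset table")
        off_map = offsets.set_index("length")["offset"]
        off = off_map.reindex(r["length"]).to_numpy(dtype=float)
        has_off = np.isfinite(off)
        qc["no_offset"] = int((~has_off).sum())
        r = r[has_off]
        a_site = r["five_prime_pos"].to_numpy() + off[has_off].astype(int)
        lo = (mod["cds_start"].reindex(r["transcript_id"]).to_numpy()
              + trim_start_nt)
        hi = (mod["cds_end"].reindex(r["transcript_id"]).to_numpy()
              - trim_end_nt)
        ok = (a_site >= lo) & (a_site < hi)
        qc["outside"] = int((~ok).sum())
        r = r[ok]
    qc["counted"] = len(r)
    counts = (r.groupby(["transcript_id", "library_id"], observed=True)
              .size().unstack(fill_value=0))
    counts = counts.reindex(index=mod.index,
                            columns=sorted(reads["library_id"].unique()),
                            fill_value=0)
    counts.index.name = "gene"
    return counts, qc


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million on raw library totals."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"library with zero total counts: {empty}")
    return counts / totals * 1e6


def filter_expressed(rpf_counts: pd.DataFrame, rna_counts: pd.DataFrame,
                     cpm_threshold: float = 0.75, min_libraries: int = 3
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep genes with cpm strictly above threshold in >= min_libraries
    footprint libraries; the retained gene set is applied to both assays."""
    keep = ((cpm(rpf_counts) > cpm_threshold).sum(axis=1)
            >= min_libraries)
    genes = rpf_counts.index[keep]
    return rpf_counts.loc[genes], rna_counts.loc[rna_counts.index.intersection(genes)]


def _tmm_pair(y_k: np.ndarray, y_r: np.ndarray, n_k: float, n_r: float,
              trim_m: float, trim_a: float) -> float:
    both = (y_k > 0) & (y_r > 0)
    yk, yr = y_k[both].astype(float), y_r[both].astype(float)
    if yk.size == 0:
        return 1.0
    m = np.log2((yk / n_k) / (yr / n_r))
    a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
    w = 1.0 / ((n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr))
    n = yk.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) \
        & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 20:
        logger.warning("TMM: only %d genes survive trimming; "
                       "falling back to untrimmed mean", int(keep.sum()))
        keep = np.ones(n, dtype=bool)
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_normalize(counts: pd.DataFrame, trim_m: float = 0.3,
                  trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Reference library: the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  M values are doubly trimmed
    (``trim_m`` of genes from each tail of M, ``trim_a`` from each tail of
    A) and averaged with inverse asymptotic-variance weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("TMM requires positive library totals")
    q75 = np.array([np.quantile(counts.iloc[:, j].to_numpy(), 0.75)
                    for j in range(counts.shape[1])]) / totals
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    y_r = counts.iloc[:, ref].to_numpy()
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(counts.iloc[:, j].to_numpy(), y_r,
                               totals[j], totals[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
            pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 cpm on TMM-scaled library sizes with a pseudocount."""
    totals = counts.sum(axis=0)
    if factors is not None:
        totals = totals * factors.reindex(counts.columns)
    return np.log2((counts + pseudocount) / totals * 1e6)


def _group_welch(mat: pd.DataFrame, cols_mut: list[str],
                 cols_wt: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t test (vectorised): returns (effect, p)."""
    from scipy import stats as sps
    xm = mat[cols_mut].to_numpy(dtype=float)
    xw = mat[cols_wt].to_numpy(dtype=float)
    n1, n2 = xm.shape[1], xw.shape[1]
    m1, m2 = xm.mean(axis=1), xw.mean(axis=1)
    v1, v2 = xm.var(axis=1, ddof=1), xw.var(axis=1, ddof=1)
    effect = m1 - m2
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = np.where(se2 == 0, np.where(effect == 0, 1.0, 0.0),
                 2.0 * sps.t.sf(np.abs(t), np.where(np.isfinite(df), df, 1.0)))
    return effect, p


def te_change(rpf_counts: pd.DataFrame, rna_counts: pd.DataFrame,
              lib_meta: pd.DataFrame, fdr_threshold: float = 0.1,
              pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene translation-efficiency change calls between two genotypes.

    ``lib_meta`` needs columns library_id, assay (RPF/RNA), genotype,
    replicate; the second genotype level in order of appearance is treated
    as the mutant.  Genes are classified at per-assay FDR < ``fdr_threshold``
    as RPF-only, RNA-only, both, or neither.
    """
    meta = lib_meta.set_index("library_id")
    genotypes = list(dict.fromkeys(lib_meta["genotype"]))
    if len(genotypes) != 2:
        raise ValueError(f"need exactly two genotypes, got {genotypes}")
    wt, mut = genotypes

    genes = rpf_counts.index.intersection(rna_counts.index)
    rpf = rpf_counts.loc[genes]
    rna = rna_counts.loc[genes]
    lc = {}
    cols: dict[tuple[str, str], list[str]] = {}
    for assay, counts in (("RPF", rpf), ("RNA", rna)):
        libs = meta[meta["assay"] == assay]
        missing_gt = {wt, mut} - set(libs["genotype"])
        if missing_gt:
            raise ValueError(f"{assay}: missing genotype level {missing_gt}")
        factors = tmm_normalize(counts[libs.index])
        lc[assay] = log_cpm(counts[libs.index], factors,
                            pseudocount=pseudocount)
        for gt in (wt, mut):
            sel = libs[libs["genotype"] == gt]
            if len(sel) < 2:
                raise ValueError(f"{assay}/{gt}: need >= 2 replicates")
            cols[(assay, gt)] = sel.index.tolist()

    rpf_lfc, rpf_p = _group_welch(lc["RPF"], cols[("RPF", mut)],
                                  cols[("RPF", wt)])
    rna_lfc, rna_p = _group_welch(lc["RNA"], cols[("RNA", mut)],
                                  cols[("RNA", wt)])

    # TE contrast: paired by replicate when the replicate design matches
    def _reps(assay, gt):
        return {meta.loc[c, "replicate"]: c for c in cols[(assay, gt)]}

    paired = all(_reps("RPF", gt).keys() == _reps("RNA", gt).keys()
                 for gt in (wt, mut))
    if paired:
        te_mat = {}
        for gt in (wt, mut):
            rp, rn = _reps("RPF", gt), _reps("RNA", gt)
            te_mat[gt] = pd.DataFrame(
                {f"te_{gt}_{r}": lc["RPF"][rp[r]] - lc["RNA"][rn[r]]
                 for r in sorted(rp)})
        te_all = pd.concat([te_mat[wt], te_mat[mut]], axis=1)
        delta_te, te_p = _group_welch(te_all, list(te_mat[mut].columns),
                                      list(te_mat[wt].columns))
    else:
        delta_te = rpf_lfc - rna_lfc
        # unpaired contrast of effects: Welch over the four groups
        from scipy import stats as sps
        var = np.zeros(len(genes))
        df_num = np.zeros(len(genes))
        df_den = np.zeros(len(genes))
        for assay, gt in cols:
            x = lc[assay][cols[(assay, gt)]].to_numpy(dtype=float)
            n = x.shape[1]
            v = x.var(axis=1, ddof=1) / n
            var += v
            df_den += v**2 / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta_te / np.sqrt(var)
            df = var**2 / df_den
        te_p = np.where(var == 0, np.where(delta_te == 0, 1.0, 0.0),
                        2.0 * sps.t.sf(np.abs(t),
                                       np.where(np.isfinite(df), df, 1.0)))

    rpf_fdr = bh_adjust(rpf_p)
    rna_fdr = bh_adjust(rna_p)
    te_fdr = bh_adjust(te_p)
    sig_rpf = rpf_fdr < fdr_threshold
    sig_rna = rna_fdr < fdr_threshold
    te_class = np.select(
        [sig_rpf & sig_rna, sig_rpf & ~sig_rna, ~sig_rpf & sig_rna],
        ["both", "RPF-only", "RNA-only"], default="neither")
    return pd.DataFrame({
        "gene": genes, "delta_te": delta_te, "te_P": te_p, "te_FDR": te_fdr,
        "rpf_lfc": rpf_lfc, "rpf_P": rpf_p, "rpf_FDR": rpf_fdr,
        "rna_lfc": rna_lfc, "rna_P": rna_p, "rna_FDR": rna_fdr,
        "te_class": te_class,
    }).set_index("gene")


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in a nucleotide sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def utr_gc_compare(te_results: pd.DataFrame, models: pd.DataFrame):
    """5'UTR GC content of down-translated vs unchanged genes (Mann-Whitney).

    Down-translated: significant footprint change (RPF-only or both) with a
    negative footprint fold change; unchanged: class 'neither'.
    """
    utr = models.set_index("transcript_id")["utr5_sequence"]
    gc = te_results.index.to_series().map(
        lambda g: gc_fraction(utr[g]) if isinstance(utr.get(g), str) else np.nan)
    down = te_results["te_class"].isin(["RPF-only", "both"]) \
        & (te_results["rpf_lfc"] < 0)
    unchanged = te_results["te_class"] == "neither"
    gc_down = gc[down].dropna().to_numpy()
    gc_unch = gc[unchanged].dropna().to_numpy()
    if gc_down.size == 0 or gc_unch.size == 0:
        raise ValueError("both groups must be non-empty for GC comparison")
    res = mann_whitney(gc_down, gc_unch)
    res.extra.update({"median_gc_down": float(np.median(gc_down)),
                      "median_gc_unchanged": float(np.median(gc_unch))})
    return res
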