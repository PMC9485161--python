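"""Peptide-to-protein aggregation and subunit-median normalization.

Turns peptide-level TMT log2 ratios (differentiated cell vs hESC reference
channel) into one normalized relative abundance per ribosomal protein per
sample.  Normalization subtracts, within each sample, the median log2 ratio
over the observed RPs of the protein's subunit (40S or 60S), which removes
sample-wide multiplicative offsets such as TMT labeling-efficiency
differences and leaves the per-subunit median at exactly zero.

An analogous path exists for mRNA abundance: TPM values are first scaled to
the hESC replicate mean per gene and then subunit-median normalized, so the
mRNA compartment joins the same abundance-matrix schema.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_annotation",
    "aggregate_peptides",
    "normalize_subunit_median",
    "normalize_rna_tpm",
]

#: columns carried through the long-format RP abundance matrix
ABUNDANCE_COLUMNS = ["sample_id", "cell_type", "replicate", "compartment",
                     "rp_id", "log2_abundance", "n_peptides", "peptide_sd"]

_META_COLS = ["sample_id", "cell_type", "replicate", "compartment"]


def load_annotation(core_only: bool = False) -> pd.DataFrame:
    """Bundled annotation of the 80 core RPs (plus the eL22L paralog row).

    Columns: rp_id, universal_name, subunit (40S/60S), is_core.
    """
    ref = importlib.resources.files("ribohet") / "data" / "rp_annotation.tsv"
    with importlib.resources.as_file(ref) as path:
        ann = pd.read_csv(path, sep="\t")
    ann["is_core"] = ann["is_core"].astype(bool)
    if core_only:
        ann = ann[ann["is_core"]].reset_index(drop=True)
    if ann["rp_id"].duplicated().any():
        raise ValueError("annotation rp_id values must be unique")
    return ann


def aggregate_peptides(peptides: pd.DataFrame,
                       method: str = "median") -> pd.DataFrame:
    """Aggregate peptide log2 ratios to one protein value per (rp, sample).

    ``peptides`` is a long table with at least sample_id, rp_id, log2_ratio
    and ideally cell_type/replicate/compartment metadata.  Missing peptide
    ratios are dropped, never imputed; an (rp, sample) pair with no observed
    peptides simply does not appear in the output.
    """
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    if "sample_id" not in peptides.columns:
        raise ValueError("peptide table must carry sample_id")
    obs = peptides.dropna(subset=["log2_ratio"]).copy()
    meta = [c for c in _META_COLS if c in obs.columns]
    keys = meta + ["rp_id"]
    grouped = obs.groupby(keys, sort=True, observed=True)["log2_ratio"]
    out = grouped.agg(log2_abundance=method, n_peptides="size",
                      peptide_sd="std").reset_index()
    return out


def _require_subunit(matrix: pd.DataFrame,
                     annotation: pd.DataFrame) -> pd.DataFrame:
    unknown = set(matrix["rp_id"]) - set(annotation["rp_id"])
    if unknown:
        raise ValueError(f"rp_id not in annotation: {sorted(unknown)}")
    return matrix.merge(annotation[["rp_id", "subunit"]], on="rp_id", how="left")


def normalize_subunit_median(matrix: pd.DataFrame, annotation: pd.DataFrame,
                             min_observed: int = 3) -> pd.DataFrame:
    """Subtract the per-(sample, subunit) median log2 abundance.

    Requires at least ``min_observed`` observed RPs per subunit per sample;
    after normalization the median over observed RPs of each subunit within
    each sample is exactly zero.  The operation is idempotent.
    """
    m = _require_subunit(matrix, annotation)
    counts = m.groupby(["sample_id", "subunit"], observed=True)[
        "log2_abundance"].count()
    bad = counts[counts < min_observed]
    if len(bad):
        sample = bad.index[0]
        raise ValueError(
            f"sample {sample[0]!r} has only {int(bad.iloc[0])} observed "
            f"{sample[1]} RPs (need >= {min_observed})")
    med = m.groupby(["sample_id", "subunit"], observed=True)[
        "log2_abundance"].transform("median")
    m["log2_abundance"] = m["log2_abundance"] - med
    return m.drop(columns=["subunit"])


def normalize_rna_tpm(tpm: pd.DataFrame, annotation: pd.DataFrame,
                      reference_cell_type: str = "hESC",
                      min_observed: int = 3) -> pd.DataFrame:
    """Normalize an RP TPM table into the shared abundance-matrix schema.

    ``tpm`` is long format: sample_id, cell_type, replicate, rp_id, tpm.
    Each RP's TPM is divided by its mean TPM over the reference (hESC)
    replicates and log2-transformed; reference samples themselves are not
    emitted.  RPs whose reference mean is zero are dropped with a warning.
    The result is then subunit-median normalized and tagged with
    compartment = "mRNA".
    """
    needed = {"sample_id", "cell_type", "replicate", "rp_id", "tpm"}
    if not needed.issubset(tpm.columns):
        raise ValueError(f"tpm table needs columns {sorted(needed)}")
    ref = tpm[tpm["cell_type"] == reference_cell_type]
    if ref.empty:
        raise ValueError(f"no reference ({reference_cell_type}) samples in table")
    ref_mean = ref.groupby("rp_id", observed=True)["tpm"].mean()
    zero = ref_mean[ref_mean <= 0].index
    if len(zero):
        logger.warning("dropping %d RPs with zero reference-mean TPM: %s",
                       len(zero), ", ".join(map(str, zero)))
    keep = tpm[(tpm["cell_type"] != reference_cell_type)
               & ~tpm["rp_id"].isin(zero)].copy()
    keep["log2_abundance"] = np.log2(
        keep["tpm"].to_numpy() / ref_mean.reindex(keep["rp_id"]).to_numpy())
    keep["compartment"] = "mRNA"
    keep["n_peptides"] = np.nan
    keep["peptide_sd"] = np.nan
    keep = keep.drop(columns=["tpm"])
    return normalize_subunit_median(keep, annotation, min_observed=min_observed)
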