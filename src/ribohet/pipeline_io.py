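"""Readers, writers and run configuration for all external formats.

All tables are TSV with headers and stable column order; coordinates are
0-based half-open everywhere inside the package, with conversions confined
to the I/O boundary.  Missing quantification values are empty cells, never
zeros or numeric sentinels (no imputation happens anywhere downstream).
Macromolecular structures (PDB or mmCIF) are parsed with gemmi; waters are
excluded and only the first-listed alternate conformer of each atom is
retained.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .structure_exposure import DEFAULT_RADIUS, VDW_RADII, AtomSet

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "KNOWN_COMPARTMENTS",
    "read_quant_table",
    "write_quant_table",
    "read_structure",
    "read_reads",
    "write_reads",
    "read_transcript_models",
    "write_transcript_models",
    "read_ct_table",
    "write_ct_table",
]

KNOWN_COMPARTMENTS = {"polysome", "cytoplasm", "whole_cell", "mRNA",
                      "free_subunit", "monosome"}


@dataclass
class RunConfig:
    """Thresholds and knobs of a pipeline run; YAML round-trip is lossless."""

    seed: int = 0
    anova_alpha: float = 0.05
    magnitude_threshold: float = 0.10
    min_cell_types: int = 2
    cpm_threshold: float = 0.75
    min_libraries: int = 3
    cds_trim_start_codons: int = 15
    cds_trim_end_codons: int = 5
    probe_radius: float = 1.4
    sasa_points: int = 960
    n_permutations: int = 9999
    fdr_threshold: float = 0.1
    aggregation: str = "median"

    def __post_init__(self) -> None:
        if not (0 < self.anova_alpha < 1) or not (0 < self.fdr_threshold < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.magnitude_threshold < 0 or self.cpm_threshold < 0:
            raise ValueError("magnitude/cpm thresholds must be >= 0")
        if min(self.min_cell_types, self.min_libraries, self.sasa_points,
               self.n_permutations) < 1:
            raise ValueError("count thresholds must be >= 1")
        if self.cds_trim_start_codons < 0 or self.cds_trim_end_codons < 0:
            raise ValueError("CDS trims must be >= 0")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.aggregation not in ("median", "mean"):
            raise ValueError("aggregation must be 'median' or 'mean'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

_QUANT_COLUMNS = ["sample_id", "compartment", "cell_type", "replicate",
                  "rp_id", "peptide_id", "log2_ratio"]


def read_quant_table(path: str | Path,
                     known_cell_types: set[str] | None = None,
                     known_compartments: set[str] | None = KNOWN_COMPARTMENTS
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide (or protein) ratio table plus per-sample metadata.

    Empty log2_ratio cells become missing values (NaN), never zeros.
    Unknown compartment/cell-type labels and duplicate
    (sample, rp, peptide) keys are validation errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str})
    missing = [c for c in _QUANT_COLUMNS if c not in df.columns
               and c != "peptide_id"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "peptide_id" not in df.columns:
        df["peptide_id"] = ""
    df["log2_ratio"] = pd.to_numeric(df["log2_ratio"], errors="raise")
    if known_compartments is not None:
        bad = sorted(set(df["compartment"]) - known_compartments)
        if bad:
            raise ValueError(f"{path}: unknown compartment labels {bad}")
    if known_cell_types is not None:
        bad = sorted(set(df["cell_type"]) - known_cell_types)
        if bad:
            raise ValueError(f"{path}: unknown cell-type labels {bad}")
    key = ["sample_id", "rp_id", "peptide_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"{path}: duplicate record for key {first}")
    meta = (df[["sample_id", "compartment", "cell_type", "replicate"]]
            .drop_duplicates().reset_index(drop=True))
    return df, meta


def write_quant_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _QUANT_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path,
                   radius_overrides: dict[str, float] | None = None,
                   strict_elements: bool = True) -> AtomSet:
    """Atoms of a PDB or mmCIF file as an AtomSet.

    Waters are excluded; for alternate locations only the first-listed
    conformer is kept.  Van der Waals radii come from the built-in table
    (C/N/O/S/P/H) plus ``radius_overrides``; an element with no known
    radius is an error unless ``strict_elements`` is off (then the default
    carbon-like radius is used).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    radii = dict(VDW_RADII)
    if radius_overrides:
        radii.update(radius_overrides)
    chain_id, res_name, res_num, element, xyz, radius = [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name == "HOH":
                continue
            seen_names: set[str] = set()
            for atom in res:
                if atom.name in seen_names:  # later altloc conformer
                    continue
                seen_names.add(atom.name)
                el = atom.element.name.upper()
                if el not in radii:
                    if strict_elements:
                        raise ValueError(
                            f"{path}: element {el!r} has no van der Waals "
                            "radius; pass radius_overrides")
                    r = DEFAULT_RADIUS
                else:
                    r = radii[el]
                chain_id.append(chain.name)
                res_name.append(res.name)
                res_num.append(res.seqid.num)
                element.append(el)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radius.append(r)
    if not xyz:
        raise ValueError(f"{path}: no atoms after filtering")
    return AtomSet(np.array(chain_id, dtype=object),
                   np.array(res_name, dtype=object),
                   np.array(res_num), np.array(element, dtype=object),
                   np.array(xyz), np.array(radius))


# ---------------------------------------------------------------------------
# reads and transcript models
# ---------------------------------------------------------------------------

def read_transcript_models(path: str | Path) -> pd.DataFrame:
    """Transcript CDS models: 0-based half-open, CDS length a codon multiple."""
    df = pd.read_csv(path, sep="\t")
    needed = ["transcript_id", "transcript_length", "cds_start", "cds_end"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[(df["cds_start"] < 0) | (df["cds_start"] >= df["cds_end"])
             | (df["cds_end"] > df["transcript_length"])]
    if len(bad):
        raise ValueError(f"{path}: invalid CDS bounds for "
                         f"{bad['transcript_id'].iloc[0]!r}")
    off = (df["cds_end"] - df["cds_start"]) % 3
    if (off != 0).any():
        t = df.loc[off != 0, "transcript_id"].iloc[0]
        raise ValueError(f"{path}: CDS length not a codon multiple for {t!r}")
    return df


def write_transcript_models(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["transcript_id", "transcript_length", "cds_start", "cds_end"]
    if "utr5_sequence" in df.columns:
        cols.append("utr5_sequence")
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_reads(path: str | Path,
               models: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read records (transcript_id, five_prime_pos, length, library_id).

    With ``models`` given, reads lying outside their transcript are a
    validation error.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["transcript_id", "five_prime_pos", "length", "library_id"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if (df["five_prime_pos"] < 0).any() or (df["length"] <= 0).any():
        raise ValueError(f"{path}: negative positions or non-positive lengths")
    if models is not None:
        tlen = models.set_index("transcript_id")["transcript_length"]
        known = df["transcript_id"].isin(tlen.index)
        end = (df.loc[known, "five_prime_pos"]
               + df.loc[known, "length"]).to_numpy()
        lim = tlen.reindex(df.loc[known, "transcript_id"]).to_numpy()
        if (end > lim).any():
            i = int(np.argmax(end > lim))
            t = df.loc[known].iloc[i]["transcript_id"]
            raise ValueError(f"{path}: read extends past transcript {t!r}")
    return df


def write_reads(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["transcript_id", "five_prime_pos", "length", "library_id"]
    df.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> pd.DataFrame:
    """qPCR Ct records; literal "Undetermined" becomes Ct = 40 with a flag."""
    df = pd.read_csv(path, sep=None, engine="python")
    needed = ["sample_id", "target", "ct"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    raw = df["ct"].astype(str).str.strip()
    und = raw.str.lower() == "undetermined"
    ct = pd.to_numeric(raw.where(~und), errors="raise")
    if ((ct <= 0) | (ct > 40)).any():
        bad = ct[(ct <= 0) | (ct > 40)].iloc[0]
        raise ValueError(f"{path}: Ct value {bad} outside (0, 40]")
    df = df.copy()
    df["ct"] = ct.fillna(40.0)
    df["undetermined"] = und.to_numpy()
    if "fraction" not in df.columns:
        df["fraction"] = np.nan
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    und = out.get("undetermined")
    out["ct"] = out["ct"].astype(object)
    if und is not None:
        out.loc[und.astype(bool), "ct"] = "Undetermined"
    cols = [c for c in ["sample_id", "target", "fraction", "ct"]
            if c in out.columns]
    out.to_csv(path, sep=",", index=False, columns=cols)
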