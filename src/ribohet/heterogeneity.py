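"""Classification of heterogeneous ribosomal proteins.

An RP is *heterogeneous* when its normalized polysomal relative abundance
varies significantly across the seven differentiated cell types (one-way
ANOVA on replicate-level log2 values, P < alpha).  A heterogeneous RP is
additionally *strong* when its median abundance changes by at least 10% on
the linear ratio scale (|2^median - 1| >= 0.10) in at least two
differentiated cell types.  Progressive changes along a lineage are scored
by ordinary least squares of replicate-level values on the ordinal stage
index, and cross-compartment concordance by the Spearman correlation of
per-cell-type medians between two compartments.

The hESC reference is the ratio denominator, not a group: by default it
enters neither the ANOVA nor the lineage regression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats_core import bh_adjust, one_way_anova, ols_slope, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "anova_per_rp",
    "classify",
    "lineage_trend",
    "cross_compartment_correlation",
    "correlation_histogram",
]


def _values_by_group(sub: pd.DataFrame) -> dict[str, np.ndarray]:
    return {ct: g["log2_abundance"].to_numpy()
            for ct, g in sub.groupby("cell_type", observed=True)}


def anova_per_rp(matrix: pd.DataFrame,
                 cell_types: list[str] | None = None) -> pd.DataFrame:
    """One-way ANOVA of log2 abundance across cell types, per RP.

    Only cell types in ``cell_types`` (default: all present) are used as
    groups; groups need >= 2 replicates, and an RP needs >= 2 usable groups
    or its P is reported missing with the reason logged.
    """
    rows = []
    for rp, sub in matrix.groupby("rp_id", observed=True):
        if cell_types is not None:
            sub = sub[sub["cell_type"].isin(cell_types)]
        groups = [v for v in _values_by_group(sub).values() if v.size >= 2]
        if len(groups) < 2:
            logger.info("RP %s: fewer than 2 cell types with >=2 replicates; "
                        "ANOVA skipped", rp)
            rows.append({"rp_id": rp, "anova_F": np.nan, "anova_P": np.nan,
                         "n_groups": len(groups)})
            continue
        res = one_way_anova(groups)
        rows.append({"rp_id": rp, "anova_F": res.statistic,
                     "anova_P": res.p_value, "n_groups": len(groups)})
    return pd.DataFrame(rows)


def classify(matrix: pd.DataFrame, anova: pd.DataFrame,
             alpha: float = 0.05, magnitude_threshold: float = 0.10,
             min_cell_types: int = 2, adjust_bh: bool = False,
             require_celltype_t: bool = False,
             reference_cell_type: str = "hESC") -> pd.DataFrame:
    """Heterogeneous / strong classification of each RP.

    heterogeneous: ANOVA P < alpha (optionally BH-adjusted first).
    strong: heterogeneous, and the per-cell-type median changes by at least
    ``magnitude_threshold`` on the linear ratio scale in at least
    ``min_cell_types`` differentiated cell types.  With
    ``require_celltype_t`` the qualifying cell types must also differ from
    zero by a one-sample t test at P < 0.05 (an alternative reading of the
    screen; off by default).
    """
    med = (matrix[matrix["cell_type"] != reference_cell_type]
           .groupby(["rp_id", "cell_type"], observed=True)["log2_abundance"]
           .agg(["median", "size"]).reset_index())
    med["linear_change"] = np.abs(2.0 ** med["median"] - 1.0)
    qualifies = med["linear_change"] >= magnitude_threshold
    if require_celltype_t:
        from scipy import stats as sps
        t_ok = []
        for _, row in med.iterrows():
            vals = matrix[(matrix["rp_id"] == row["rp_id"])
                          & (matrix["cell_type"] == row["cell_type"])][
                "log2_abundance"].to_numpy()
            if vals.size < 2 or np.var(vals) == 0:
                t_ok.append(vals.size >= 2 and vals.mean() != 0)
                continue
            t_ok.append(sps.ttest_1samp(vals, 0.0).pvalue < 0.05)
        qualifies &= np.asarray(t_ok)
    n_qual = med[qualifies].groupby("rp_id", observed=True).size()

    out = anova.copy()
    p = out["anova_P"].to_numpy(dtype=float)
    if adjust_bh:
        ok = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        adj[ok] = bh_adjust(p[ok])
        p = adj
    out["is_heterogeneous"] = p < alpha
    out["n_strong_cell_types"] = out["rp_id"].map(n_qual).fillna(0).astype(int)
    out["strong_flag"] = (out["is_heterogeneous"]
                          & (out["n_strong_cell_types"] >= min_cell_types))
    max_change = med.groupby("rp_id", observed=True)["linear_change"].max()
    out["max_linear_change"] = out["rp_id"].map(max_change)
    return out


def lineage_trend(matrix: pd.DataFrame, stages: list[str],
                  include_reference: bool = False,
                  reference_cell_type: str = "hESC") -> pd.DataFrame:
    """OLS slope of replicate-level log2 abundance on ordinal lineage stage.

    ``stages`` lists differentiated cell types in lineage order (stage 1,
    2, ...).  With ``include_reference`` the hESC reference enters as stage
    0 at value 0 (its own relative abundance).  RPs observed in fewer than
    3 stages get missing trend fields.
    """
    stage_idx = {ct: i + 1 for i, ct in enumerate(stages)}
    rows = []
    for rp, sub in matrix.groupby("rp_id", observed=True):
        sub = sub[sub["cell_type"].isin(stage_idx)]
        x = sub["cell_type"].map(stage_idx).to_numpy(dtype=float)
        y = sub["log2_abundance"].to_numpy(dtype=float)
        if include_reference:
            n_ref = int((matrix[matrix["rp_id"] == rp]["cell_type"]
                         == reference_cell_type).sum())
            x = np.concatenate([x, np.zeros(max(n_ref, 1))])
            y = np.concatenate([y, np.zeros(max(n_ref, 1))])
        n_stages = len(np.unique(x))
        if n_stages < 3:
            rows.append({"rp_id": rp, "trend_slope": np.nan,
                         "trend_P": np.nan, "n_stages": n_stages})
            continue
        res = ols_slope(x, y)
        rows.append({"rp_id": rp, "trend_slope": res.statistic,
                     "trend_P": res.p_value, "n_stages": n_stages})
    return pd.DataFrame(rows)


def cross_compartment_correlation(matrix_a: pd.DataFrame,
                                  matrix_b: pd.DataFrame,
                                  min_points: int = 4) -> pd.DataFrame:
    """Per-RP Spearman correlation of per-cell-type medians between compartments.

    RPs with fewer than ``min_points`` shared cell types are omitted with a
    warning.  Average-rank tie handling via the shared Spearman kernel.
    """
    med_a = (matrix_a.groupby(["rp_id", "cell_type"], observed=True)
             ["log2_abundance"].median().rename("a"))
    med_b = (matrix_b.groupby(["rp_id", "cell_type"], observed=True)
             ["log2_abundance"].median().rename("b"))
    joined = pd.concat([med_a, med_b], axis=1, join="inner").reset_index()
    rows = []
    for rp, sub in joined.groupby("rp_id", observed=True):
        if len(sub) < min_points:
            logger.warning("RP %s: only %d shared cell types (<%d); "
                           "correlation omitted", rp, len(sub), min_points)
            continue
        rho = spearman(sub["a"].to_numpy(), sub["b"].to_numpy())
        rows.append({"rp_id": rp, "spearman_rho": rho, "n_cell_types": len(sub)})
    return pd.DataFrame(rows, columns=["rp_id", "spearman_rho", "n_cell_types"])


def correlation_histogram(rho: pd.Series | np.ndarray,
                          bin_width: float = 0.1) -> pd.DataFrame:
    """Counts of correlation values in fixed-width bins over [-1, 1].

    The closing bin includes its right edge so the counts always sum to the
    number of input values.
    """
    vals = np.asarray(rho, dtype=float)
    if np.any((vals < -1) | (vals > 1)):
        raise ValueError("correlation values must lie in [-1, 1]")
    n_bins = int(round(2.0 / bin_width))
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
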