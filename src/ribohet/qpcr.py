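"""RT-qPCR arithmetic: relative expression, gradient distributions, IP enrichment.

All computations assume perfect doubling per cycle (amplification
efficiency 2), so a Ct difference of d maps to a 2^-d fold change.  An
"Undetermined" reaction carries Ct = 40 as a conservative overestimate of
expression; it is acceptable for a target of interest but an error for any
normalizer (reference gene, spike-in, or control transcript).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "relative_expression",
    "gradient_distribution",
    "ip_enrichment",
]


def _lookup_ct(ct: pd.DataFrame, sample: str, target: str,
               fraction=None) -> tuple[float, bool]:
    sel = (ct["sample_id"] == sample) & (ct["target"] == target)
    if fraction is not None:
        sel &= ct["fraction"] == fraction
    rows = ct[sel]
    where = f"sample {sample!r}, target {target!r}" + (
        f", fraction {fraction}" if fraction is not None else "")
    if len(rows) == 0:
        raise ValueError(f"no Ct record for {where}")
    if len(rows) > 1:
        raise ValueError(f"multiple Ct records for {where}")
    row = rows.iloc[0]
    return float(row["ct"]), bool(row.get("undetermined", False))


def relative_expression(ct: pd.DataFrame, target: str, reference: str,
                        efficiency: float = 2.0) -> pd.Series:
    """Fold expression of ``target`` relative to ``reference`` per sample.

    fold = efficiency^-(Ct_target - Ct_reference).  An undetermined
    reference cannot normalize and raises; an undetermined target yields
    the conservative floor implied by Ct = 40.
    """
    out = {}
    for sample in ct["sample_id"].unique():
        sub = ct[ct["sample_id"] == sample]
        if target not in set(sub["target"]) or reference not in set(sub["target"]):
            continue
        ct_t, _ = _lookup_ct(ct, sample, target)
        ct_r, und_r = _lookup_ct(ct, sample, reference)
        if und_r:
            raise ValueError(
                f"reference {reference!r} undetermined in sample {sample!r}")
        out[sample] = float(efficiency ** -(ct_t - ct_r))
    if not out:
        raise ValueError(f"no sample measures both {target!r} and {reference!r}")
    return pd.Series(out, name="fold_expression")


def gradient_distribution(ct: pd.DataFrame, target: str, spike_target: str,
                          sample: str | None = None,
                          efficiency: float = 2.0) -> pd.Series:
    """Share of a transcript's total abundance in each gradient fraction.

    Per fraction f: v_f = efficiency^-(Ct_target,f - Ct_spike,f); shares are
    v_f normalized to sum to 1 over all fractions.  The spike-in must be
    determined in every fraction.
    """
    if sample is None:
        cands = ct.loc[ct["target"] == target, "sample_id"].unique()
        if len(cands) != 1:
            raise ValueError("sample must be given when the table holds "
                             f"multiple samples for {target!r}: {list(cands)}")
        sample = cands[0]
    sub = ct[ct["sample_id"] == sample]
    fracs = sorted(sub.loc[sub["target"] == target, "fraction"].dropna().unique())
    if not fracs:
        raise ValueError(f"no fractions found for target {target!r}")
    v = []
    for f in fracs:
        ct_t, _ = _lookup_ct(sub, sample, target, fraction=f)
        ct_s, und_s = _lookup_ct(sub, sample, spike_target, fraction=f)
        if und_s:
            raise ValueError(f"spike-in undetermined in fraction {f}")
        v.append(efficiency ** -(ct_t - ct_s))
    v = np.asarray(v, dtype=float)
    shares = pd.Series(v / v.sum(), index=pd.Index(fracs, name="fraction"),
                       name="share")
    assert abs(shares.sum() - 1.0) < 1e-9
    return shares


def ip_enrichment(ct: pd.DataFrame, target: str, control_target: str,
                  elution_sample: str, input_sample: str,
                  efficiency: float = 2.0) -> float:
    """Ribosome-IP association: control-normalized elution over input.

    ratio = [eff^-(Ct_target,elu - Ct_ctrl,elu)] /
            [eff^-(Ct_target,in - Ct_ctrl,in)].
    """
    ct_te, _ = _lookup_ct(ct, elution_sample, target)
    ct_ce, und_ce = _lookup_ct(ct, elution_sample, control_target)
    ct_ti, _ = _lookup_ct(ct, input_sample, target)
    ct_ci, und_ci = _lookup_ct(ct, input_sample, control_target)
    if und_ce or und_ci:
        raise ValueError(f"control {control_target!r} undetermined")
    elu = efficiency ** -(ct_te - ct_ce)
    inp = efficiency ** -(ct_ti - ct_ci)
    return float(elu / inp)
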