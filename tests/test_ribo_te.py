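"""Offset calibration, CDS-trim boundaries, TMM and TE-change calls."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ribohet import ribo_te as rt
from ribohet import synthetic_data as sd


# ----------------------------------------------------------------- calibration
def test_calibrate_planted_distance_plus_four(tiny_reads):
    model, make = tiny_reads
    reads = pd.concat([make(100 - 12, n=300)])  # d = 12 at length 28
    off = rt.calibrate_offsets(reads, model, min_support=100)
    assert off.set_index("length").loc[28, "offset"] == 16


def test_calibrate_bimodal_tie_prefers_smaller_distance(tiny_reads):
    model, make = tiny_reads
    reads = pd.concat([make(100 - 12, n=100), make(100 - 13, n=100)])
    off = rt.calibrate_offsets(reads, model, min_support=100)
    assert off.set_index("length").loc[28, "offset"] == 12 + 4


def test_calibrate_low_support_dropped_with_warning(tiny_reads, caplog):
    model, make = tiny_reads
    reads = pd.concat([make(100 - 12, length=28, n=300),
                       make(100 - 13, length=30, n=10)])
    with caplog.at_level("WARNING"):
        off = rt.calibrate_offsets(reads, model, min_support=200)
    assert 30 not in set(off["length"])
    assert any("30" in r.message for r in caplog.records)
    with pytest.raises(ValueError):
        rt.calibrate_offsets(make(100 - 12, n=10), model, min_support=200)


def test_calibrate_recovers_generator_truth(ribo_dataset):
    _, reads, models, _, truth = ribo_dataset
    rpf = reads[reads.library_id.str.startswith("RPF")]
    off = rt.calibrate_offsets(rpf, models)
    assert dict(zip(off["length"], off["offset"])) == truth.offsets


# -------------------------------------------------------------------- counting
OFF28 = pd.DataFrame({"length": [28], "offset": [16], "support": [1000]})


@pytest.mark.parametrize("a_site,counted", [
    (100 + 44, False),   # one nt short of the 15-codon start trim
    (100 + 45, True),    # first counted position
    (400 - 16, True),    # last counted position
    (400 - 15, False),   # half-open end bound (5-codon end trim)
])
def test_count_cds_trim_boundaries(tiny_reads, a_site, counted):
    model, make = tiny_reads
    reads = make(a_site - 16)  # offset 16 puts the A site at a_site
    counts, qc = rt.count_cds(reads, model, OFF28, "RPF")
    assert counts.to_numpy().sum() == (1 if counted else 0)
    assert qc["outside"] == (0 if counted else 1)


def test_count_conservation_and_unknown_transcripts(tiny_reads):
    model, make = tiny_reads
    reads = pd.concat([make(100 - 16 + 45, n=5), make(0, n=3)])
    stray = make(10, n=2)
    stray["transcript_id"] = "unknown"
    reads = pd.concat([reads, stray])
    counts, qc = rt.count_cds(reads, model, OFF28, "RPF")
    assert qc["no_model"] == 2
    assert qc["counted"] + qc["no_model"] + qc["outside"] + qc["no_offset"] \
        == len(reads)
    assert counts.to_numpy().sum() == qc["counted"]


def test_count_rna_counts_whole_transcript(tiny_reads):
    model, make = tiny_reads
    reads = pd.concat([make(0, length=50), make(550, length=50)])
    counts, qc = rt.count_cds(reads, model, None, "RNA")
    assert counts.to_numpy().sum() == 2


def test_count_zero_jitter_equals_generator_truth(ribo_dataset):
    _, reads, models, _, truth = ribo_dataset
    rpf = reads[reads.library_id.str.startswith("RPF")]
    rna = reads[reads.library_id.str.startswith("RNA")]
    off = rt.calibrate_offsets(rpf, models)
    rpf_counts, _ = rt.count_cds(rpf, models, off, "RPF")
    rna_counts, _ = rt.count_cds(rna, models, None, "RNA")
    tr = truth.counts
    np.testing.assert_array_equal(rpf_counts.to_numpy(),
                                  tr[rpf_counts.columns].to_numpy())
    np.testing.assert_array_equal(rna_counts.to_numpy(),
                                  tr[rna_counts.columns].to_numpy())


# ------------------------------------------------------------------- filtering
def _counts(rows, libs=6):
    return pd.DataFrame(rows, columns=[f"L{i}" for i in range(libs)])


def test_filter_strictly_greater_than_threshold():
    # library total 1e6 so count == cpm
    filler = np.full((1, 6), 1_000_000 - 1)
    rpf = pd.DataFrame(np.vstack([[0.75] * 6, filler]).astype(int) + (
        np.vstack([[0] * 6, [0] * 6]).astype(int)))
    rpf.iloc[0] = 0  # rebuild precisely below
    rpf = pd.DataFrame({f"L{i}": [0, 0] for i in range(6)})
    rpf.iloc[0] = 1          # cpm of gene 0
    rpf.iloc[1] = 999_999    # filler keeps totals at 1e6
    rpf.index = ["g_edge", "g_fill"]
    # gene at cpm exactly 1.0 > 0.75 in all 6 -> retained
    rna = rpf.copy()
    kept, _ = rt.filter_expressed(rpf, rna, cpm_threshold=0.75)
    assert "g_edge" in kept.index
    # now push the edge gene to exactly cpm == threshold: removed (strict >)
    rpf2 = rpf * 0
    rpf2.iloc[0] = 3          # total 4e6 per lib below
    rpf2.iloc[1] = 3_999_997
    kept2, _ = rt.filter_expressed(rpf2, rpf2, cpm_threshold=0.75)
    assert "g_edge" not in kept2.index


def test_filter_requires_min_libraries():
    rpf = pd.DataFrame({f"L{i}": [0, 100] for i in range(6)},
                       index=["g", "fill"])
    for i in range(3):
        rpf.loc["g", f"L{i}"] = 10  # cpm >> 0.75 in exactly 3 libraries
    kept, _ = rt.filter_expressed(rpf, rpf.copy())
    assert "g" in kept.index
    rpf.loc["g", "L2"] = 0          # now only 2 libraries
    kept, _ = rt.filter_expressed(rpf, rpf.copy())
    assert "g" not in kept.index


def test_filter_empty_library_is_error():
    rpf = pd.DataFrame({"L0": [0, 0], "L1": [5, 5]})
    with pytest.raises(ValueError):
        rt.filter_expressed(rpf, rpf.copy())


# ------------------------------------------------------------------------ TMM
def tmm_oracle(counts: np.ndarray, ref: int, k: int) -> float:
    """Independent brute-force evaluation of the doubly trimmed weighted
    mean of M values (sorting-based, no rank shortcuts)."""
    nk, nr = counts[:, k].sum(), counts[:, ref].sum()
    yk, yr = counts[:, k].astype(float), counts[:, ref].astype(float)
    both = (yk > 0) & (yr > 0)
    yk, yr = yk[both], yr[both]
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
    n = len(m)
    lo = int(np.floor(n * 0.3))
    loa = int(np.floor(n * 0.05))
    m_sorted = np.argsort(np.argsort(m, kind="stable"), kind="stable")
    a_sorted = np.argsort(np.argsort(a, kind="stable"), kind="stable")
    keep = ((m_sorted >= lo) & (m_sorted <= n - 1 - lo)
            & (a_sorted >= loa) & (a_sorted <= n - 1 - loa))
    return 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def test_tmm_identical_libraries_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.integers(1, 500, size=200)
    counts = pd.DataFrame({f"L{i}": col for i in range(4)})
    f = rt.tmm_normalize(counts)
    np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-12)


def test_tmm_pure_depth_change_gives_unit_factors():
    rng = np.random.default_rng(1)
    col = rng.integers(10, 500, size=300)
    counts = pd.DataFrame({"L0": col, "L1": col * 2, "L2": col})
    f = rt.tmm_normalize(counts)
    np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-9)


def test_tmm_matches_bruteforce_oracle_on_planted_de():
    rng = np.random.default_rng(2)
    base = rng.negative_binomial(5, 0.02, size=(200, 4)).astype(float) + 1
    base[:20, 1] *= 4.0  # 10% asymmetric DE in library 1
    counts = pd.DataFrame(base.astype(int),
                          columns=[f"L{i}" for i in range(4)])
    f = rt.tmm_normalize(counts)
    totals = counts.to_numpy().sum(axis=0)
    q75 = np.array([np.quantile(counts.iloc[:, j], 0.75)
                    for j in range(4)]) / totals
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    raw = np.ones(4)
    for k in range(4):
        if k != ref:
            raw[k] = tmm_oracle(counts.to_numpy(), ref, k)
    expected = raw / np.exp(np.mean(np.log(raw)))
    np.testing.assert_allclose(f.to_numpy(), expected, rtol=0.02)


def test_tmm_matches_edger(tmp_path):
    """Cross-check factors against edgeR's calcNormFactors."""
    rng = np.random.default_rng(3)
    base = rng.negative_binomial(4, 0.01, size=(150, 4)).astype(float) + 1
    base[:15, 2] *= 3.0
    counts = pd.DataFrame(base.astype(int),
                          columns=[f"L{i}" for i in range(4)])
    csv = tmp_path / "counts.csv"
    counts.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.csv("{csv}"))
        f <- calcNormFactors(x, method="TMM")
        cat(paste(f, collapse=","))
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    theirs = np.array([float(v) for v in out.stdout.strip().split(",")])
    mine = rt.tmm_normalize(counts).to_numpy()
    np.testing.assert_allclose(mine, theirs, rtol=0.01)


# ------------------------------------------------------------------ TE change
def _lib_meta():
    rows = []
    for assay in ("RPF", "RNA"):
        for gt in ("WT", "LOF"):
            for rep in (1, 2, 3):
                rows.append({"library_id": f"{assay}_{gt}_rep{rep}",
                             "assay": assay, "genotype": gt,
                             "replicate": rep})
    return pd.DataFrame(rows)


def test_te_change_identical_genotypes_no_calls():
    rng = np.random.default_rng(4)
    meta = _lib_meta()
    base = rng.integers(50, 500, size=(100, 3))
    rpf = pd.DataFrame(np.hstack([base, base]),
                       columns=meta[meta.assay == "RPF"]["library_id"])
    rna = pd.DataFrame(np.hstack([base, base]),
                       columns=meta[meta.assay == "RNA"]["library_id"])
    res = rt.te_change(rpf, rna, meta)
    np.testing.assert_allclose(res["delta_te"], 0.0, atol=1e-9)
    assert (res["te_class"] == "neither").all()


def test_te_change_rna_only_gene_classified_rna_only():
    rng = np.random.default_rng(5)
    meta = _lib_meta()
    n = 200
    lam = rng.integers(100, 800, size=n).astype(float)
    cols = {}
    for _, lib in meta.iterrows():
        mult = np.ones(n)
        if lib.genotype == "LOF":
            mult[0] = 4.0  # gene 0: 4x up in BOTH assays -> RNA change only
        cols[lib.library_id] = rng.poisson(lam * mult)
    rpf = pd.DataFrame({c: cols[c] for c in
                        meta[meta.assay == "RPF"]["library_id"]})
    rna = pd.DataFrame({c: cols[c] for c in
                        meta[meta.assay == "RNA"]["library_id"]})
    res = rt.te_change(rpf, rna, meta)
    assert res["te_class"].iloc[0] == "both"  # up in both assays
    # now plant a change in RNA only: TE down, RNA up
    cols = {}
    for _, lib in meta.iterrows():
        mult = np.ones(n)
        if lib.genotype == "LOF" and lib.assay == "RNA":
            mult[1] = 4.0
        cols[lib.library_id] = rng.poisson(lam * mult)
    rpf = pd.DataFrame({c: cols[c] for c in
                        meta[meta.assay == "RPF"]["library_id"]})
    rna = pd.DataFrame({c: cols[c] for c in
                        meta[meta.assay == "RNA"]["library_id"]})
    res = rt.te_change(rpf, rna, meta)
    assert res["te_class"].iloc[1] == "RNA-only"
    assert res["delta_te"].iloc[1] < -1.5


def test_te_change_requires_two_genotypes():
    meta = _lib_meta()
    meta["genotype"] = "WT"
    rpf = pd.DataFrame(np.ones((5, 6), dtype=int), columns=meta.library_id[:6])
    with pytest.raises(ValueError):
        rt.te_change(rpf, rpf.copy(), meta)


# ----------------------------------------------------------------------- 5'UTR
def test_gc_fraction_examples():
    assert rt.gc_fraction("GGCC") == 1.0
    assert rt.gc_fraction("AATT") == 0.0
    assert rt.gc_fraction("GATC") == 0.5
    with pytest.raises(ValueError):
        rt.gc_fraction("")


def test_utr_gc_higher_in_down_translated_genes(ribo_dataset):
    _, reads, models, meta, truth = ribo_dataset
    rpf = reads[reads.library_id.str.startswith("RPF")]
    rna = reads[reads.library_id.str.startswith("RNA")]
    off = rt.calibrate_offsets(rpf, models)
    rc, _ = rt.count_cds(rpf, models, off, "RPF")
    nc, _ = rt.count_cds(rna, models, None, "RNA")
    rc, nc = rt.filter_expressed(rc, nc)
    te = rt.te_change(rc, nc, meta)
    res = rt.utr_gc_compare(te, models)
    assert res.p_value < 0.05
    assert res.extra["median_gc_down"] > res.extra["median_gc_unchanged"]
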