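"""Region classification, P-site shifting, densities, peaks, ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcprof import (
    GenomeAnnotation,
    PeakTable,
    Region,
    SyntheticConfig,
    build_profiles,
    classify_region,
    classify_regions,
    correlate_peak_tables,
    footprints_to_frame,
    frame_fractions,
    gene_densities,
    generate_transcriptome,
    length_histogram,
    load_alignments,
    peak_height,
    psite_shift,
    region_fractions,
    simulate_footprints,
    utr3_orf_ratio,
    write_footprints,
)
from tcprof.profiles import AlignedFootprint

from conftest import make_model


def frame(rows):
    return footprints_to_frame([AlignedFootprint(*r) for r in rows])


def profile(rows, ann, sample="s", assay="ssu40"):
    return build_profiles(frame(rows), ann, sample, assay)


# -- P-site shift -----------------------------------------------------------


def test_psite_shift_constants(toy_model):
    s = toy_model.stop_start
    assert psite_shift(s - 14, "ssu40") == s
    assert psite_shift(0, "ribo80") == 13
    assert psite_shift(123, "none") == 123


# -- region classification --------------------------------------------------


def test_classify_region_examples(toy_model):
    # utr5=50, cds=300: start window [47, 56), stop window [341, 350)
    assert classify_region(44, 30, toy_model) is Region.START
    s = toy_model.stop_start
    assert classify_region(s - 40, 30, toy_model) is Region.ORF
    assert classify_region(s + 10, 30, toy_model) is Region.UTR3
    assert classify_region(0, 20, toy_model) is Region.UTR5
    assert classify_region(s - 6, 9, toy_model) is Region.STOP


def brute_force_region(five_prime, length, model):
    """Independent interval-intersection oracle."""
    a, s = model.start_codon_pos, model.stop_start
    fp_nt = set(range(five_prime, five_prime + length))
    if fp_nt & set(range(a - 3, a + 6)):
        return Region.START
    if fp_nt & set(range(s - 6, s + 3)):
        return Region.STOP
    if five_prime < a:
        return Region.UTR5
    if five_prime < s + 3:
        return Region.ORF
    return Region.UTR3


def test_classify_region_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    models = [
        make_model(f"G{i}", utr5=int(u), cds=int(c), utr3=int(t), seed=i)
        for i, (u, c, t) in enumerate(
            zip(rng.integers(30, 200, 20), 3 * rng.integers(30, 300, 20), rng.integers(40, 200, 20))
        )
    ]
    for _ in range(2000):
        m = models[rng.integers(0, len(models))]
        length = int(rng.integers(15, 60))
        fp = int(rng.integers(0, m.length - length))
        assert classify_region(fp, length, m) is brute_force_region(fp, length, m)


def test_vectorized_classification_agrees_with_scalar(small_world):
    _, ann, _, ps = small_world
    sub = ps.reads.head(2000)
    vec = classify_regions(sub, ann)
    for i, row in sub.head(200).iterrows():
        assert vec[i] is classify_region(row.five_prime, row.length, ann[row.gene_id])


# -- region fractions -------------------------------------------------------


def test_region_fractions_sum_exactly_one(small_world):
    _, ann, _, ps = small_world
    fractions, counts = region_fractions(ps, ann)
    assert sum(fractions.values()) == 1  # exact rational arithmetic
    assert sum(counts.values()) == len(ps.reads)


def test_region_fractions_degenerate_cases(toy_model, toy_ann):
    a = toy_model.start_codon_pos
    fr, _ = region_fractions(frame([("TOY1", a - 14, 30)]), toy_ann)
    assert float(fr[Region.START]) == 1.0
    fr, _ = region_fractions(frame([("TOY1", toy_model.stop_start + 20, 30)]), toy_ann)
    assert float(fr[Region.UTR3]) == 1.0 and float(fr[Region.ORF]) == 0.0
    with pytest.raises(ValueError):
        region_fractions(frame([]), toy_ann)


def test_region_mixture_recovery_from_generator():
    """A known planted mixture is recovered within multinomial error."""
    mixture = {"utr5_bg": 0.1, "start_peak": 0.6, "orf_bg": 0.2, "stop_peak": 0.05,
               "utr3_bg": 0.05, "utr3_aug": 0.0, "queued_80s": 0.0}
    cfg = SyntheticConfig(n_genes=60, occupancy_40s=mixture, utr3_aug_fraction=0.0)
    ann, truth = generate_transcriptome(cfg, seed=5)
    n = 100_000
    reads = simulate_footprints(ann, truth, cfg, "wt", "ssu40", n_reads=n, seed=6)
    fractions, _ = region_fractions(reads, ann)
    expected = truth.expected_region_mixture("wt", "ssu40")
    for region, label in [(Region.UTR5, "UTR5"), (Region.START, "START"), (Region.ORF, "ORF"),
                          (Region.STOP, "STOP"), (Region.UTR3, "UTR3")]:
        p = expected[label]
        tol = 5 * np.sqrt(p * (1 - p) / n)
        assert abs(float(fractions[region]) - p) < tol


# -- length histogram -------------------------------------------------------


def test_length_histogram_single_and_empty(toy_ann):
    h = length_histogram(frame([("TOY1", 10, 32), ("TOY1", 20, 32)]))
    assert h.loc[32, "count"] == 2 and h["count"].sum() == 2
    h0 = length_histogram(frame([]))
    assert (h0["count"] == 0).all()


def test_length_histogram_bimodal_modes_recovered():
    cfg = SyntheticConfig(n_genes=30, minor21_fraction=0.2)
    ann, truth = generate_transcriptome(cfg, seed=2)
    reads = simulate_footprints(ann, truth, cfg, "wt", "ssu40", n_reads=10_000, seed=3)
    h = length_histogram(reads)["count"]
    assert h.loc[26:].idxmax() == 32  # main mode
    assert h.loc[21] == pytest.approx(0.2 * h.sum(), rel=0.1)  # minor class share
    region_h = length_histogram(reads, ann, by_region=True)
    assert region_h.to_numpy().sum() == 10_000


# -- densities --------------------------------------------------------------


def test_orf_density_closed_form():
    """Uniform 1 read/nt over the trimmed ORF gives the exact rpkm."""
    m = make_model("U1", utr5=50, cds=1032, utr3=100)
    ann = GenomeAnnotation([m])
    a, s3 = m.start_codon_pos, m.utr3_start
    lo, hi = a + 15, s3 - 15  # shifted-position window
    rows = [("U1", p - 14, 30) for p in range(lo, hi)]
    ps = build_profiles(frame(rows), ann, "s", "ssu40")
    dens = gene_densities(ps, ann, genes=["U1"])
    n_window = hi - lo
    total = len(rows)
    expected = (n_window / total * 1e6) / ((m.cds_len - 30) / 1000)
    assert dens.loc["U1", "orf_rpkm"] == pytest.approx(expected)
    assert dens.loc["U1", "utr3_rpkm"] == 0.0


def test_orf_end_trim_excludes_boundary_reads(toy_ann, toy_model):
    a = toy_model.start_codon_pos
    # shifted position lands at A+5, inside the first 15 nt of the ORF
    ps = profile([("TOY1", a + 5 - 14, 30)], toy_ann)
    dens = gene_densities(ps, toy_ann, genes=["TOY1"])
    assert dens.loc["TOY1", "orf_rpkm"] == 0.0
    # and at A+15 it is included
    ps = profile([("TOY1", a + 15 - 14, 30)], toy_ann)
    dens = gene_densities(ps, toy_ann, genes=["TOY1"])
    assert dens.loc["TOY1", "orf_rpkm"] > 0


def test_zero_length_region_is_nan():
    m = make_model("NOUTR", utr5=0, cds=300, utr3=80)
    ann = GenomeAnnotation([m])
    ps = build_profiles(frame([("NOUTR", 40, 30)]), ann, "s", "ssu40")
    dens = gene_densities(ps, ann, genes=["NOUTR"])
    assert np.isnan(dens.loc["NOUTR", "utr5_rpkm"])
    # the 3'UTR is always extended, so it stays defined
    assert np.isfinite(dens.loc["NOUTR", "utr3_rpkm"])


def test_density_scaling_properties(small_world):
    """Doubling every count doubles rpm numerators; rpkm is invariant when
    the denominator doubles too."""
    _, ann, _, ps = small_world
    dens = gene_densities(ps, ann)
    doubled = ps.reads.copy()
    doubled["weight"] = 2
    ps2 = build_profiles(doubled, ann, "s", "ssu40")
    dens2 = gene_densities(ps2, ann)  # total_mapped also doubles
    pd.testing.assert_frame_equal(dens, dens2)
    from tcprof.profiles import ProfileSet

    ps3 = ProfileSet("s", "ssu40", doubled, total_mapped=ps.total_mapped)
    dens3 = gene_densities(ps3, ann)
    assert np.allclose(dens3["orf_rpkm"].dropna(), 2 * dens["orf_rpkm"].dropna())


# -- peak heights -----------------------------------------------------------


def test_peak_height_stalled_reads(toy_ann, toy_model):
    s = toy_model.stop_start
    ps = profile([("TOY1", s - 14, 32)] * 7, toy_ann)
    pt = peak_height(ps, toy_ann, "stop", genes=["TOY1"])
    assert pt.table.loc["TOY1", "peak_count"] == 7
    assert pt.table.loc["TOY1", "peak_rpm"] == pytest.approx(7e6 / 7)


def test_peak_height_outside_window_is_zero(toy_ann, toy_model):
    s = toy_model.stop_start
    ps = profile([("TOY1", s - 20, 32)] * 3, toy_ann)  # shifted to S-6
    pt = peak_height(ps, toy_ann, "stop", genes=["TOY1"])
    assert pt.table.loc["TOY1", "peak_count"] == 0


def test_peak_height_uniform_background_equals_window_width(toy_ann, toy_model):
    rows = [("TOY1", p, 20) for p in range(0, toy_model.length - 20)]
    ps = profile(rows, toy_ann)
    pt = peak_height(ps, toy_ann, "stop", genes=["TOY1"])
    assert pt.table.loc["TOY1", "peak_count"] == 5


def test_peak_height_translation_equivariance():
    """Shifting footprints and annotation together leaves peaks unchanged."""
    k = 30
    m1 = make_model("T", utr5=60, cds=300, utr3=90, seed=9)
    m2 = make_model("T", utr5=60 + k, cds=300, utr3=90, seed=9)
    ann1, ann2 = GenomeAnnotation([m1]), GenomeAnnotation([m2])
    rows1 = [("T", m1.stop_start - 14 + d, 30) for d in (-2, 0, 1, 5)]
    rows2 = [(g, f + k, ln) for g, f, ln in rows1]
    p1 = peak_height(profile(rows1, ann1), ann1, "stop", genes=["T"])
    p2 = peak_height(profile(rows2, ann2), ann2, "stop", genes=["T"])
    assert p1.table["peak_count"].tolist() == p2.table["peak_count"].tolist()


# -- 3'UTR : ORF ratio ------------------------------------------------------


def _uniform_profile(ann, m, orf_per_nt, utr3_per_nt, total=None):
    rows = []
    a, s3 = m.start_codon_pos, m.utr3_start
    for p in range(a + 15, s3 - 15):
        rows += [(m.gene_id, p - 13, 30)] * orf_per_nt
    for p in range(s3, m.length - 30):
        rows += [(m.gene_id, p - 13, 30)] * utr3_per_nt
    return build_profiles(frame(rows), ann, "s", "ribo80")


def test_utr3_orf_ratio_thresholds():
    m = make_model("R1", utr5=50, cds=900, utr3=120)
    ann = GenomeAnnotation([m])
    ps = _uniform_profile(ann, m, 2, 1)
    out = utr3_orf_ratio(ps, ann, genes=["R1"])
    dens = gene_densities(ps, ann, genes=["R1"])
    assert "R1" in out.index
    assert out.loc["R1", "ratio"] == pytest.approx(
        dens.loc["R1", "utr3_rpkm"] / dens.loc["R1", "orf_rpkm"]
    )
    # raising the ORF threshold above the gene's density drops it
    out2 = utr3_orf_ratio(ps, ann, min_orf_rpkm=dens.loc["R1", "orf_rpkm"] * 1.01, genes=["R1"])
    assert "R1" not in out2.index
    # thresholds are inclusive: exactly at the bound is kept
    out3 = utr3_orf_ratio(
        ps, ann, min_orf_rpkm=float(dens.loc["R1", "orf_rpkm"]),
        min_utr3_rpkm=float(dens.loc["R1", "utr3_rpkm"]), genes=["R1"],
    )
    assert "R1" in out3.index


def test_utr3_enhancement_shifts_ratio_distribution():
    """3'UTR occupancy boosted in the mutant raises the ratio medians."""
    cfg = SyntheticConfig(n_genes=40, utr3_fold_change=10.0)
    ann, truth = generate_transcriptome(cfg, seed=21)
    wt = simulate_footprints(ann, truth, cfg, "wt", "ribo80", n_reads=80_000, seed=22)
    mut = simulate_footprints(ann, truth, cfg, "tma_dd", "ribo80", n_reads=80_000, seed=23)
    r_wt = utr3_orf_ratio(build_profiles(wt, ann, "wt", "ribo80"), ann)
    r_mut = utr3_orf_ratio(build_profiles(mut, ann, "mut", "ribo80"), ann)
    assert r_mut["ratio"].median() > 3 * r_wt["ratio"].median()


# -- frames -----------------------------------------------------------------


def test_frame_fractions_pure_and_uniform(toy_ann, toy_model):
    a = toy_model.start_codon_pos
    rows = [("TOY1", a + 18 + 3 * k - 13, 30) for k in range(40)]
    fr, _ = frame_fractions(profile(rows, toy_ann, assay="ribo80"), toy_ann, genes=["TOY1"])
    assert fr.tolist() == [1.0, 0.0, 0.0]
    rng = np.random.default_rng(0)
    rows = [("TOY1", int(p) - 13, 30) for p in rng.integers(a + 15, toy_model.utr3_start - 15, 9000)]
    fr, _ = frame_fractions(profile(rows, toy_ann, assay="ribo80"), toy_ann, genes=["TOY1"])
    assert np.allclose(fr, 1 / 3, atol=0.02)


def test_frame_fractions_generator_periodicity():
    cfg = SyntheticConfig(n_genes=30, frame0_prob=0.9)
    ann, truth = generate_transcriptome(cfg, seed=31)
    reads = simulate_footprints(ann, truth, cfg, "wt", "ribo80", n_reads=30_000, seed=32)
    fr, counts = frame_fractions(build_profiles(reads, ann, "s", "ribo80"), ann)
    assert abs(fr[0] - 0.9) < 0.02
    assert counts.sum() > 10_000


# -- correlation ------------------------------------------------------------


def _peak_table(values, anchor="stop", sample="s"):
    table = pd.DataFrame(
        {"peak_count": values, "peak_rpm": values, "truncated": False},
        index=[f"G{i}" for i in range(len(values))],
    ).rename_axis("gene_id")
    return PeakTable(sample=sample, anchor=anchor, table=table)


def test_correlation_perfect_for_scaled_tables():
    rng = np.random.default_rng(1)
    x = rng.lognormal(3, 1, 300) + 1
    res = correlate_peak_tables(_peak_table(x), _peak_table(2 * x))
    assert res.r2 == pytest.approx(1.0)
    assert res.n == 300


def test_correlation_near_zero_for_permuted_tables():
    rng = np.random.default_rng(2)
    x = rng.lognormal(3, 1, 500) + 1
    res = correlate_peak_tables(_peak_table(x), _peak_table(rng.permutation(x)))
    # null spread of r^2 for n=500 is ~1/n
    assert res.r2 < 25 / 500


def test_correlation_errors():
    a = _peak_table([1, 2, 3])
    b = PeakTable("s", "stop", a.table.rename(index={"G0": "H0", "G1": "H1", "G2": "H2"}))
    with pytest.raises(ValueError):
        correlate_peak_tables(a, b)  # disjoint genes
    with pytest.raises(ValueError):
        correlate_peak_tables(_peak_table([0, 0, 5]), _peak_table([1, 1, 5]))  # < 3 after filter


# -- alignment ingestion ----------------------------------------------------


def test_load_alignments_bed(tmp_path, toy_ann):
    path = tmp_path / "aln.bed"
    path.write_text(
        "TOY1\t44\t74\tread1\n"  # five_prime 44, length 30
        "TOY1\t100\t132\tread2\n"
        "GHOST\t10\t40\tread3\n"  # unknown gene
        "TOY1\t10\t20\tread4\n"  # 10 nt: below 40S size range
    )
    reads, stats = load_alignments(path, toy_ann, "ssu40")
    assert stats["retained"] == 2 and stats["unknown_gene"] == 1 and stats["size_filtered"] == 1
    assert reads.iloc[0].five_prime == 44 and reads.iloc[0].length == 30


def test_load_alignments_bed_matches_hand_built(tmp_path, toy_ann):
    rows = [("TOY1", 5 + 7 * i, 28 + (i % 5)) for i in range(10)]
    src = frame(rows)
    path = tmp_path / "round.bed"
    write_footprints(src, path)
    back, stats = load_alignments(path, toy_ann, "ssu40")
    pd.testing.assert_frame_equal(back, src)
    assert stats["retained"] == 10


def test_load_alignments_malformed_record(tmp_path, toy_ann):
    path = tmp_path / "bad.bed"
    path.write_text("TOY1\t44\tseventy\tread1\n")
    with pytest.raises(ValueError, match="record 1"):
        load_alignments(path, toy_ann, "ssu40")


def test_load_alignments_sam(tmp_path, toy_ann, toy_model):
    import pysam

    path = str(tmp_path / "aln.sam")
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "TOY1", "LN": toy_model.length}]}
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        a = pysam.AlignedSegment(fh.header)
        a.query_name = "read1"
        a.query_sequence = "A" * 30
        a.reference_id = 0
        a.reference_start = 44
        a.cigarstring = "30M"
        a.mapping_quality = 40
        a.flag = 0
        fh.write(a)
    reads, stats = load_alignments(path, toy_ann, "ssu40")
    assert stats["retained"] == 1
    assert reads.iloc[0].five_prime == 44 and reads.iloc[0].length == 30
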