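"""Per-transcript count tracks, region classification and quantitation.

Footprint collections are held as pandas DataFrames with columns
``gene_id``, ``five_prime`` (0-based transcript position of the
footprint 5' end), ``length`` and ``weight``; :class:`AlignedFootprint`
is the single-record view.  A :class:`ProfileSet` bundles one sample's
footprints with its rpm denominator and caches per-gene 5'-end count
tracks.

P-site positions are obtained by shifting footprint 5' ends by a fixed
per-assay offset: +14 nt for 40S (ssu40) footprints, +13 nt for 80S
(ribo80), 0 for mRNA-seq.  Region classification uses the unshifted
whole-footprint interval against a 9-nt window centered on the start
codon and a 9-nt window ending with the stop codon at its 3' end.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, TranscriptModel, usable_genes
from .config import DEFAULTS

logger = logging.getLogger(__name__)

READ_COLUMNS = ["gene_id", "five_prime", "length", "weight"]

#: fixed P-site offsets (nt added to the footprint 5' end)
P_SITE_SHIFT = DEFAULTS["psite_shift"]
SIZE_RANGE = DEFAULTS["size_range"]


class Region(str, Enum):
    UTR5 = "UTR5"
    START = "START"
    ORF = "ORF"
    STOP = "STOP"
    UTR3 = "UTR3"


@dataclass
class AlignedFootprint:
    """One mapped footprint in transcript coordinates."""

    gene_id: str
    five_prime: int
    length: int
    weight: int = 1


def footprints_to_frame(footprints) -> pd.DataFrame:
    """Build the canonical footprint DataFrame from records or tuples."""
    rows = [
        (fp.gene_id, fp.five_prime, fp.length, fp.weight)
        if isinstance(fp, AlignedFootprint)
        else tuple(fp)
        for fp in footprints
    ]
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    return df.astype({"five_prime": np.int64, "length": np.int64, "weight": np.int64})


class ProfileSet:
    """One sample's footprints plus per-gene 5'-end count tracks.

    ``total_mapped`` is the rpm denominator: the summed weight of all
    retained footprints on annotated transcripts after deduplication and
    size selection.
    """

    def __init__(self, sample: str, assay: str, reads: pd.DataFrame, total_mapped: float | None = None):
        if assay not in P_SITE_SHIFT:
            raise ValueError(f"unknown assay {assay!r}")
        missing = set(READ_COLUMNS) - set(reads.columns)
        if missing:
            raise ValueError(f"footprint frame lacks columns {sorted(missing)}")
        self.sample = sample
        self.assay = assay
        self.reads = reads.reset_index(drop=True)
        self.total_mapped = float(total_mapped if total_mapped is not None else reads["weight"].sum())
        self._tracks: dict[str, np.ndarray] = {}
        self._by_gene = dict(tuple(self.reads.groupby("gene_id", observed=True, sort=False)))

    @property
    def shift(self) -> int:
        return P_SITE_SHIFT[self.assay]

    def gene_reads(self, gene_id: str) -> pd.DataFrame:
        return self._by_gene.get(gene_id, self.reads.iloc[0:0])

    def track(self, model: TranscriptModel, shifted: bool = False) -> np.ndarray:
        """Per-position 5'-end (or P-site) count vector for one gene."""
        key = (model.gene_id, shifted)
        if key not in self._tracks:
            sub = self.gene_reads(model.gene_id)
            pos = sub["five_prime"].to_numpy()
            if shifted:
                pos = pos + self.shift
            vec = np.zeros(model.length, dtype=float)
            ok = (pos >= 0) & (pos < model.length)
            np.add.at(vec, pos[ok], sub["weight"].to_numpy(dtype=float)[ok])
            self._tracks[key] = vec
        return self._tracks[key]

    def rpm_track(self, model: TranscriptModel, shifted: bool = False) -> np.ndarray:
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be > 0 for normalized output")
        return self.track(model, shifted=shifted) * (1e6 / self.total_mapped)


def build_profiles(
    reads: pd.DataFrame,
    ann: GenomeAnnotation,
    sample: str,
    assay: str,
    length_range: tuple[int, int] | None = None,
) -> ProfileSet:
    """Assemble a :class:`ProfileSet`, optionally restricting lengths.

    The rpm denominator is the summed weight after the optional length
    filter; reads on genes absent from the annotation must already have
    been dropped (see :func:`load_alignments`).
    """
    if length_range is not None:
        lo, hi = length_range
        reads = reads[(reads["length"] >= lo) & (reads["length"] <= hi)]
    return ProfileSet(sample=sample, assay=assay, reads=reads)


# ---------------------------------------------------------------------------
# Alignment ingestion
# ---------------------------------------------------------------------------


class AlignmentParseError(ValueError):
    pass


def load_alignments(
    path: str | Path,
    ann: GenomeAnnotation,
    assay: str,
    fmt: str | None = None,
) -> tuple[pd.DataFrame, Counter]:
    """Read transcript-space alignments into the footprint frame.

    Supports SAM/BAM (reference names are gene ids) and the BED-like
    tabular dialect ``gene_id <tab> start <tab> end <tab> read_id`` with
    0-based half-open coordinates.  The per-assay size filter is
    re-applied; reads on unknown genes or outside transcript bounds are
    dropped and counted.
    """
    stats_counter: Counter = Counter()
    if fmt is None:
        fmt = "sam" if str(path).endswith((".sam", ".bam")) else "bed"
    records: list[tuple[str, int, int]] = []
    if fmt == "sam":
        import pysam

        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode) as fh:
            for i, rec in enumerate(fh.fetch(until_eof=True), start=1):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    stats_counter["not_primary"] += 1
                    continue
                length = rec.reference_length
                if length is None or length <= 0:
                    raise AlignmentParseError(f"{path}: record {i} has no aligned length")
                records.append((rec.reference_name, rec.reference_start, length))
    else:
        with open(path) as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise AlignmentParseError(f"{path}: record {i}: expected >= 3 fields")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise AlignmentParseError(f"{path}: record {i}: malformed coordinates") from exc
                if end <= start or start < 0:
                    raise AlignmentParseError(f"{path}: record {i}: invalid interval {start}-{end}")
                records.append((fields[0], start, end - start))

    lo, hi = SIZE_RANGE[assay] if assay in SIZE_RANGE else (1, 10**9)
    rows = []
    for gene, start, length in records:
        if gene not in ann:
            stats_counter["unknown_gene"] += 1
            continue
        if not (lo <= length <= hi):
            stats_counter["size_filtered"] += 1
            continue
        if start + length > ann[gene].length:
            stats_counter["out_of_bounds"] += 1
            continue
        rows.append((gene, start, length, 1))
        stats_counter["retained"] += 1
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    return df.astype({"five_prime": np.int64, "length": np.int64, "weight": np.int64}), stats_counter


def write_footprints(reads: pd.DataFrame, path: str | Path) -> None:
    """Emit the BED-like alignment dialect (gene, start, end, read id)."""
    out = reads.copy()
    out["end"] = out["five_prime"] + out["length"]
    out["read_id"] = [f"fp{i}" for i in range(len(out))]
    out[["gene_id", "five_prime", "end", "read_id"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# P-site shift and region classification
# ---------------------------------------------------------------------------


def psite_shift(five_prime, assay: str):
    """Shift footprint 5' ends to P-site positions (vectorized).

    Positions shifted beyond the transcript end are retained; callers
    decide inclusion (windowed operations here simply never count them).
    """
    return five_prime + P_SITE_SHIFT[assay]


def classify_region(five_prime: int, length: int, model: TranscriptModel) -> Region:
    """Assign one footprint to UTR5/START/ORF/STOP/UTR3.

    START if the unshifted footprint interval intersects the 9-nt window
    centered on the start codon, [A-3, A+6); else STOP if it intersects
    the 9-nt window ending with the stop codon, [S-6, S+3); otherwise the
    region containing the unshifted 5' end.  Precedence START > STOP can
    only matter for tiny CDSs and is logged when exercised.
    """
    a, s = model.start_codon_pos, model.stop_start
    lo, hi = five_prime, five_prime + length
    in_start = lo < a + 6 and hi > a - 3
    in_stop = lo < s + 3 and hi > s - 6
    if in_start:
        if in_stop:
            logger.debug("footprint on %s overlaps both start and stop windows", model.gene_id)
        return Region.START
    if in_stop:
        return Region.STOP
    if five_prime < a:
        return Region.UTR5
    if five_prime < s + 3:
        return Region.ORF
    return Region.UTR3


def classify_regions(reads: pd.DataFrame, ann: GenomeAnnotation) -> pd.Series:
    """Vectorized :func:`classify_region` over a footprint frame."""
    out = np.empty(len(reads), dtype=object)
    fp = reads["five_prime"].to_numpy()
    ln = reads["length"].to_numpy()
    for gene, idx in reads.groupby("gene_id", observed=True, sort=False).indices.items():
        model = ann[gene]
        a, s = model.start_codon_pos, model.stop_start
        lo = fp[idx]
        hi = lo + ln[idx]
        in_start = (lo < a + 6) & (hi > a - 3)
        in_stop = (lo < s + 3) & (hi > s - 6) & ~in_start
        res = np.empty(len(idx), dtype=object)
        res[lo < a] = Region.UTR5
        res[(lo >= a) & (lo < s + 3)] = Region.ORF
        res[lo >= s + 3] = Region.UTR3
        res[in_stop] = Region.STOP
        res[in_start] = Region.START
        out[idx] = res
    return pd.Series(out, index=reads.index, name="region")


def region_fractions(
    reads: pd.DataFrame | ProfileSet,
    ann: GenomeAnnotation,
    genes: list[str] | None = None,
) -> tuple[dict[Region, Fraction], dict[Region, int]]:
    """Proportion of footprints mapping to each mRNA region.

    Fractions are exact rationals over the classified footprints on the
    given genes (default: all usable genes), so they sum to 1 exactly.
    """
    if isinstance(reads, ProfileSet):
        reads = reads.reads
    if genes is None:
        genes = usable_genes(ann, "quantitation")
    sub = reads[reads["gene_id"].isin(genes)]
    if len(sub) == 0:
        raise ValueError("no classified footprints on the given genes")
    regions = classify_regions(sub, ann)
    counts = {r: 0 for r in Region}
    weights = sub["weight"].to_numpy()
    for region, idx in regions.groupby(regions).groups.items():
        counts[region] = int(weights[sub.index.get_indexer(idx)].sum())
    total = sum(counts.values())
    fractions = {r: Fraction(c, total) for r, c in counts.items()}
    return fractions, counts


def length_histogram(
    reads: pd.DataFrame | ProfileSet,
    ann: GenomeAnnotation | None = None,
    by_region: bool = False,
    length_range: tuple[int, int] = (15, 80),
) -> pd.DataFrame:
    """Footprint-length histogram, optionally split by mRNA region."""
    if isinstance(reads, ProfileSet):
        reads = reads.reads
    lo, hi = length_range
    lengths = np.arange(lo, hi + 1)
    if not by_region:
        counts = reads.groupby("length")["weight"].sum()
        return pd.DataFrame({"count": counts.reindex(lengths, fill_value=0)}).rename_axis("length")
    if ann is None:
        raise ValueError("by_region requires an annotation")
    regions = classify_regions(reads, ann)
    df = pd.DataFrame({"length": reads["length"], "weight": reads["weight"], "region": [r.value for r in regions]})
    pivot = df.pivot_table(index="length", columns="region", values="weight", aggfunc="sum", fill_value=0)
    pivot = pivot.reindex(lengths, fill_value=0)
    for region in Region:
        if region.value not in pivot.columns:
            pivot[region.value] = 0
    return pivot[[r.value for r in Region]]


# ---------------------------------------------------------------------------
# Densities, peaks, ratios, frames
# ---------------------------------------------------------------------------


def _window_rpm(ps: ProfileSet, model: TranscriptModel, lo: int, hi: int) -> float:
    """Summed shifted-position rpm in [lo, hi) clipped to the transcript."""
    track = ps.rpm_track(model, shifted=True)
    lo, hi = max(lo, 0), min(hi, model.length)
    if hi <= lo:
        return 0.0
    return float(track[lo:hi].sum())


def gene_densities(
    ps: ProfileSet,
    ann: GenomeAnnotation,
    genes: list[str] | None = None,
    orf_end_trim: int | None = None,
    utr3_extension: int | None = None,
) -> pd.DataFrame:
    """Per-gene ORF / 5'UTR / 3'UTR footprint densities in rpkm.

    P-site-shifted positions are used throughout.  The ORF window trims
    ``orf_end_trim`` (default 15) nt from each end to exclude initiating
    and terminating ribosomes; the 3'UTR is extended ``utr3_extension``
    (default 25) nt past its annotated endpoint so that footprints partly
    protecting poly(A) are accounted for (the extension contributes to
    the length denominator; in transcript space no reads can map past the
    annotated transcript end).  A region of non-positive length yields
    NaN for that gene/region.
    """
    trim = DEFAULTS["orf_end_trim"] if orf_end_trim is None else orf_end_trim
    ext = DEFAULTS["utr3_extension"] if utr3_extension is None else utr3_extension
    if genes is None:
        genes = usable_genes(ann, "quantitation")
    rows = []
    for gene in genes:
        m = ann[gene]
        a, s3 = m.start_codon_pos, m.utr3_start
        orf_len = m.cds_len - 2 * trim
        orf = _window_rpm(ps, m, a + trim, s3 - trim) / (orf_len / 1000) if orf_len > 0 else np.nan
        utr5 = _window_rpm(ps, m, 0, a) / (m.utr5_len / 1000) if m.utr5_len > 0 else np.nan
        utr3_len = m.utr3_len + ext
        utr3 = _window_rpm(ps, m, s3, s3 + utr3_len) / (utr3_len / 1000) if utr3_len > 0 else np.nan
        rows.append((gene, orf, utr5, utr3))
    return pd.DataFrame(rows, columns=["gene_id", "orf_rpkm", "utr5_rpkm", "utr3_rpkm"]).set_index("gene_id")


@dataclass
class PeakTable:
    """Per-gene peak quantitation around the start or stop codon."""

    sample: str
    anchor: str  # "start" | "stop"
    table: pd.DataFrame = field(repr=False)  # index gene_id; peak_count, peak_rpm, truncated

    def __post_init__(self) -> None:
        if self.anchor not in ("start", "stop"):
            raise ValueError(f"anchor must be start or stop, got {self.anchor!r}")


def peak_height(
    ps: ProfileSet,
    ann: GenomeAnnotation,
    anchor: str,
    genes: list[str] | None = None,
    halfwidth: int | None = None,
) -> PeakTable:
    """Sum P-site-shifted 5'-end counts in the 5-nt window on the anchor codon.

    The window is [C-2, C+2] (inclusive) where C is the first nt of the
    start or stop codon; windows truncated by transcript bounds are
    flagged in the ``truncated`` column.
    """
    hw = DEFAULTS["peak_halfwidth"] if halfwidth is None else halfwidth
    if genes is None:
        genes = usable_genes(ann, "quantitation")
    rows = []
    for gene in genes:
        m = ann[gene]
        c = m.start_codon_pos if anchor == "start" else m.stop_start
        lo, hi = c - hw, c + hw + 1
        truncated = lo < 0 or hi > m.length
        track = ps.track(m, shifted=True)
        count = float(track[max(lo, 0) : min(hi, m.length)].sum())
        rows.append((gene, count, count * 1e6 / ps.total_mapped, truncated))
    table = pd.DataFrame(rows, columns=["gene_id", "peak_count", "peak_rpm", "truncated"]).set_index("gene_id")
    return PeakTable(sample=ps.sample, anchor=anchor, table=table)


def utr3_orf_ratio(
    ps: ProfileSet,
    ann: GenomeAnnotation,
    min_orf_rpkm: float | None = None,
    min_utr3_rpkm: float | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene 3'UTR:ORF footprint density ratio (80S readthrough signal).

    Genes must pass both inclusion thresholds (inclusive; defaults 5 rpkm
    in the ORF and 0.5 rpkm in the 3'UTR).
    """
    min_orf = DEFAULTS["min_orf_rpkm"] if min_orf_rpkm is None else min_orf_rpkm
    min_utr3 = DEFAULTS["min_utr3_rpkm"] if min_utr3_rpkm is None else min_utr3_rpkm
    dens = gene_densities(ps, ann, genes=genes)
    keep = (dens["orf_rpkm"] >= min_orf) & (dens["utr3_rpkm"] >= min_utr3)
    out = dens.loc[keep, ["orf_rpkm", "utr3_rpkm"]].copy()
    out["ratio"] = out["utr3_rpkm"] / out["orf_rpkm"]
    return out


def frame_fractions(
    ps: ProfileSet,
    ann: GenomeAnnotation,
    genes: list[str] | None = None,
    orf_end_trim: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reading-frame distribution of P-site positions in ORF interiors.

    Frame is ``(p - A) mod 3`` for shifted positions p within the
    end-trimmed ORF.  Returns (fractions, counts) over frames 0/1/2.
    """
    trim = DEFAULTS["orf_end_trim"] if orf_end_trim is None else orf_end_trim
    if genes is None:
        genes = usable_genes(ann, "quantitation")
    counts = np.zeros(3, dtype=float)
    sub = ps.reads[ps.reads["gene_id"].isin(genes)]
    for gene, grp in sub.groupby("gene_id", observed=True, sort=False):
        m = ann[gene]
        p = psite_shift(grp["five_prime"].to_numpy(), ps.assay)
        ok = (p >= m.start_codon_pos + trim) & (p < m.utr3_start - trim)
        frames = (p[ok] - m.start_codon_pos) % 3
        counts += np.bincount(frames, weights=grp["weight"].to_numpy(dtype=float)[ok], minlength=3)
    total = counts.sum()
    if total == 0:
        raise ValueError("no P-site positions in ORF interiors")
    return counts / total, counts


@dataclass
class CorrelationResult:
    r2: float
    n: int
    genes: list[str]


def correlate_peak_tables(a: PeakTable, b: PeakTable, min_count: float = 1.0) -> CorrelationResult:
    """Pearson R^2 of log-transformed peak counts on the shared gene set.

    Genes below ``min_count`` in either table are dropped first (log of
    zero is undefined; default floor 1 count).
    """
    joined = a.table[["peak_count"]].join(b.table[["peak_count"]], lsuffix="_a", rsuffix="_b", how="inner")
    joined = joined[(joined["peak_count_a"] >= min_count) & (joined["peak_count_b"] >= min_count)]
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} shared genes after filtering; need >= 3")
    r, _ = stats.pearsonr(np.log10(joined["peak_count_a"]), np.log10(joined["peak_count_b"]))
    return CorrelationResult(r2=float(r**2), n=len(joined), genes=list(joined.index))
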