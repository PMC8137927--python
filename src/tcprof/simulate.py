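"""Synthetic transcriptomes and footprint libraries with recorded truth.

The generator emulates the statistical structure the analysis assumes:
footprint 5'-end distributions with peaks at start codons (stalled 48S:
5' end at A-14 for 40S data, A-13 for 80S), at stop codons (unrecycled
40S: 5' end at S-14), at queued-80S offsets behind stalled complexes
(5' ends at S-46 with satellites at S-43/S-49, i.e. -49/-46/-52 nt from
the 3'UTR start), and at planted 3'UTR AUGs; footprint-length
distributions with 3'-end variability only (a ~32-nt main mode plus a
minor 21-nt class for 40S libraries, ~28 nt for 80S); 3-nt periodicity
of ORF-mapping 80S reads; and the linker/UMI/barcode read structure for
preprocessing tests.

Background components are planted clear of the start/stop overlap
windows so region labels are unambiguous and every expected statistic is
computable in closed form from :class:`GroundTruth` (which records the
final per-gene, per-component sampling probabilities).  Genotypes map to
occupancy reweightings: ``tma_dd`` multiplies stop peaks by
``stop_fold_change`` times a per-penultimate-codon multiplier and boosts
3'UTR and queued-80S occupancy; ``rpl11b_d`` boosts start peaks.  When
the boosted mass allows it, unboosted components are rescaled so both
samples keep the same total and the expected rpm fold equals the
configured fold exactly; otherwise the whole mixture is renormalized
(and the truth matrix reflects the realized fold).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, STOP_CODONS, TranscriptModel
from .preprocess import LinkerSpec
from .profiles import READ_COLUMNS, P_SITE_SHIFT

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3)) if c not in STOP_CODONS
)  # 61 codons

COMPONENTS = ("utr5_bg", "start_peak", "orf_bg", "stop_peak", "utr3_bg", "utr3_aug", "queued_80s")

#: component -> region label it is planted in (for closed-form mixtures)
COMPONENT_REGION = {
    "utr5_bg": "UTR5",
    "start_peak": "START",
    "orf_bg": "ORF",
    "stop_peak": "STOP",
    "utr3_bg": "UTR3",
    "utr3_aug": "UTR3",
    "queued_80s": "ORF",
}

#: WT region proportions reported for real 40S libraries (5'UTR, start,
#: ORF, stop, 3'UTR) -- available as an explicit occupancy preset.
PAPER_WT_REGION_MIXTURE = {
    "utr5_bg": 0.089,
    "start_peak": 0.59,
    "orf_bg": 0.273,
    "stop_peak": 0.025,
    "utr3_bg": 0.023,
    "utr3_aug": 0.0,
    "queued_80s": 0.0,
}


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the package's study conditions."""

    n_genes: int = 120
    utr5_range: tuple[int, int] = (60, 240)
    cds_range: tuple[int, int] = (330, 1500)  # nt, rounded to codon multiples
    utr3_range: tuple[int, int] = (90, 240)
    #: WT 40S occupancy weights.  Start-codon-dominated like real 40S
    #: libraries; the stop-peak weight sits at the upper end of the
    #: admissible range so per-gene stop-peak counts stay stable at the
    #: default depth (see the methods note; PAPER_WT_REGION_MIXTURE gives
    #: the observed real-data proportions for region-fraction emulation).
    occupancy_40s: dict[str, float] = field(
        default_factory=lambda: {
            "utr5_bg": 0.09,
            "start_peak": 0.58,
            "orf_bg": 0.24,
            "stop_peak": 0.04,
            "utr3_bg": 0.04,
            "utr3_aug": 0.01,
            "queued_80s": 0.0,
        }
    )
    #: WT 80S occupancy: elongation-dominated.
    occupancy_80s: dict[str, float] = field(
        default_factory=lambda: {
            "utr5_bg": 0.01,
            "start_peak": 0.06,
            "orf_bg": 0.80,
            "stop_peak": 0.08,
            "utr3_bg": 0.02,
            "utr3_aug": 0.01,
            "queued_80s": 0.02,
        }
    )
    stop_fold_change: float = 20.0  # tma_dd stop-peak rpm fold vs WT
    codon_multipliers: dict[str, float] = field(default_factory=dict)  # penultimate codon -> extra fold
    start_fold_change: float = 2.0  # rpl11b_d start-peak boost
    utr3_fold_change: float = 3.0  # tma_dd 3'UTR background/AUG boost
    queued_fold_change: float = 6.0  # tma_dd queued-80S boost
    length_mode_40s: int = 32
    length_spread_40s: float = 3.0
    length_clip_40s: tuple[int, int] = (26, 45)
    minor21_fraction: float = 0.08  # minor short 40S footprint class
    length_mode_80s: int = 28
    length_spread_80s: float = 1.5
    length_clip_80s: tuple[int, int] = (25, 34)
    queued_offset: int = 46  # nt upstream of the stop codon first nt
    queued_satellite: int = 3
    queued_main_weight: float = 0.6
    frame0_prob: float = 0.9  # 3-nt periodicity of ORF background
    utr3_aug_fraction: float = 0.6  # genes with a planted 3'UTR AUG
    dorf_fraction: float = 0.3  # of planted AUGs, fraction extended to a dORF
    balanced_codons: bool = True  # cycle penultimate codons over all 61
    #: SD (log scale) of per-gene expression multipliers; 0 = uniform
    #: expression, ~1 spans roughly an order of magnitude like real mRNAs
    expression_dispersion: float = 0.0
    reads_per_sample: int = 100_000

    def validate(self) -> None:
        for name in ("utr5_range", "cds_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SyntheticConfigError(f"{name}: infeasible range ({lo}, {hi})")
        if self.utr5_range[0] < 20:
            raise SyntheticConfigError("utr5_range must start >= 20 nt (start peaks need room)")
        if self.cds_range[0] < 60:
            raise SyntheticConfigError("cds_range must start >= 60 nt")
        if self.utr3_range[0] < 70:
            raise SyntheticConfigError("utr3_range must start >= 70 nt (3'UTR peaks need room)")
        if self.reads_per_sample <= 0:
            raise SyntheticConfigError("reads_per_sample must be > 0")
        for occ in (self.occupancy_40s, self.occupancy_80s):
            if set(occ) - set(COMPONENTS):
                raise SyntheticConfigError(f"unknown occupancy component in {sorted(occ)}")
            if any(w < 0 for w in occ.values()):
                raise SyntheticConfigError("occupancy weights must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to recompute expected statistics in closed form."""

    gene_ids: list[str]
    lengths: pd.DataFrame  # index gene_id; utr5_len, cds_len, utr3_len
    penultimate: dict[str, str]
    stop_codons: dict[str, str]
    utr3_aug_positions: dict[str, list[int]]  # planted AUG starts (transcript coords)
    dorf_stop_positions: dict[str, list[int]]
    utr5_motifs: dict[str, list[int]] = field(default_factory=dict)  # scanned AUGs
    utr3_motifs: dict[str, list[int]] = field(default_factory=dict)
    #: per-gene expression multipliers (mean-1 scaled at sampling time)
    expression: pd.Series | None = None
    #: (genotype, assay) -> (n_genes x n_components) sampling probabilities
    probabilities: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    fastq_unique_counts: dict[str, int] = field(default_factory=dict)
    fastq_total_counts: dict[str, int] = field(default_factory=dict)

    def component_probs(self, genotype: str, assay: str) -> np.ndarray:
        return self.probabilities[(genotype, assay)]

    def expected_region_mixture(self, genotype: str, assay: str) -> dict[str, float]:
        probs = self.component_probs(genotype, assay)
        mix: dict[str, float] = {"UTR5": 0.0, "START": 0.0, "ORF": 0.0, "STOP": 0.0, "UTR3": 0.0}
        for j, comp in enumerate(COMPONENTS):
            mix[COMPONENT_REGION[comp]] += float(probs[:, j].sum())
        return mix

    def expected_stop_ratio(self, mut_genotype: str, assay: str = "ssu40", wt_genotype: str = "wt") -> pd.Series:
        """Expected per-gene mutant/WT stop-peak rpm fold (equal depths)."""
        j = COMPONENTS.index("stop_peak")
        mut = self.component_probs(mut_genotype, assay)[:, j]
        wt = self.component_probs(wt_genotype, assay)[:, j]
        return pd.Series(mut / wt, index=self.gene_ids)


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _scrub_motif(seq: np.ndarray, lo: int, hi: int, keep: set[int], motif: str = "ATG") -> None:
    """Remove accidental motif occurrences fully inside [lo, hi)."""
    text = "".join(seq[lo:hi])
    i = text.find(motif)
    while i != -1:
        if lo + i not in keep:
            seq[lo + i + 1] = "C" if seq[lo + i + 1] != "C" else "G"
            text = "".join(seq[lo:hi])
            i = text.find(motif, i)
        else:
            i = text.find(motif, i + 1)


def generate_transcriptome(
    cfg: SyntheticConfig, seed: int | np.random.Generator | None = 0
) -> tuple[GenomeAnnotation, GroundTruth]:
    """Random transcriptome with controlled codons and planted 3'UTR AUGs.

    Penultimate codons cycle over all 61 sense codons when
    ``balanced_codons`` is set (so with ``n_genes`` a multiple of 61
    every codon reaches the same count); accidental AUGs in UTRs are
    scrubbed so the planted 3'UTR AUG positions are the exact truth.
    Deterministic per seed.
    """
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models: list[TranscriptModel] = []
    truth = GroundTruth(
        gene_ids=[], lengths=pd.DataFrame(), penultimate={}, stop_codons={},
        utr3_aug_positions={}, dorf_stop_positions={},
    )
    lengths_rows = []
    for i in range(cfg.n_genes):
        gene = f"SYNG{i:04d}"
        utr5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        cds = int(rng.integers(cfg.cds_range[0] // 3, cfg.cds_range[1] // 3 + 1)) * 3
        utr3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        total = utr5 + cds + utr3
        seq = _random_seq(rng, total)
        a = utr5
        s = utr5 + cds - 3
        seq[a : a + 3] = list("ATG")
        stop = STOP_CODONS[rng.integers(0, 3)]
        seq[s : s + 3] = list(stop)
        if cfg.balanced_codons:
            penult = SENSE_CODONS[i % len(SENSE_CODONS)]
        else:
            penult = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
        seq[s - 3 : s] = list(penult)

        aug_positions: list[int] = []
        dorf_stops: list[int] = []
        if rng.random() < cfg.utr3_aug_fraction:
            lo = s + 3 + 17  # stalled 40S at the AUG stays clear of the stop window
            hi = total - 50
            if hi > lo:
                q = int(rng.integers(lo, hi))
                seq[q : q + 3] = list("ATG")
                aug_positions.append(q)
                if rng.random() < cfg.dorf_fraction and q + 15 <= total:
                    # short dORF: AUG + 3 codons + stop
                    dorf_stop = q + 12
                    seq[dorf_stop : dorf_stop + 3] = list(STOP_CODONS[rng.integers(0, 3)])
                    dorf_stops.append(dorf_stop)
        _scrub_motif(seq, 0, utr5, keep=set())
        _scrub_motif(seq, s + 3, total, keep=set(aug_positions))
        # re-assert the planted AUGs (scrub may not touch them, but be safe)
        for q in aug_positions:
            seq[q : q + 3] = list("ATG")

        sequence = "".join(seq)
        models.append(
            TranscriptModel(gene_id=gene, utr5_len=utr5, cds_len=cds, utr3_len=utr3, sequence=sequence)
        )
        truth.gene_ids.append(gene)
        truth.penultimate[gene] = penult
        truth.stop_codons[gene] = stop
        truth.utr3_aug_positions[gene] = aug_positions
        truth.dorf_stop_positions[gene] = dorf_stops
        truth.utr5_motifs[gene] = _scan_all(sequence[:utr5], "ATG", 0)
        truth.utr3_motifs[gene] = _scan_all(sequence[s + 3 :], "ATG", s + 3)
        lengths_rows.append((gene, utr5, cds, utr3))
    truth.lengths = pd.DataFrame(
        lengths_rows, columns=["gene_id", "utr5_len", "cds_len", "utr3_len"]
    ).set_index("gene_id")
    if cfg.expression_dispersion > 0:
        factors = rng.lognormal(0.0, cfg.expression_dispersion, size=cfg.n_genes)
    else:
        factors = np.ones(cfg.n_genes)
    truth.expression = pd.Series(factors, index=truth.gene_ids)
    return GenomeAnnotation(models), truth


def _scan_all(text: str, motif: str, offset: int) -> list[int]:
    hits, i = [], text.find(motif)
    while i != -1:
        hits.append(i + offset)
        i = text.find(motif, i + 1)
    return hits


# ---------------------------------------------------------------------------
# Footprint simulation
# ---------------------------------------------------------------------------


def _genotype_matrix(
    ann: GenomeAnnotation, truth: GroundTruth, cfg: SyntheticConfig, genotype: str, assay: str
) -> np.ndarray:
    """Per-gene, per-component sampling probabilities (rows sum to truth)."""
    base = dict(cfg.occupancy_40s if assay == "ssu40" else cfg.occupancy_80s)
    n = len(truth.gene_ids)
    mat = np.tile(np.array([base.get(c, 0.0) for c in COMPONENTS]) / n, (n, 1))
    if truth.expression is not None:
        expr = truth.expression.to_numpy()
        mat *= (expr / expr.mean())[:, None]
    j_aug, j_bg3 = COMPONENTS.index("utr3_aug"), COMPONENTS.index("utr3_bg")
    # genes without a planted 3'UTR AUG reassign that mass to 3'UTR background
    for i, gene in enumerate(truth.gene_ids):
        if not truth.utr3_aug_positions[gene]:
            mat[i, j_bg3] += mat[i, j_aug]
            mat[i, j_aug] = 0.0

    boosted = np.zeros(len(COMPONENTS), dtype=bool)
    if genotype == "wt":
        pass
    elif genotype == "tma_dd":
        j_stop = COMPONENTS.index("stop_peak")
        mults = np.array(
            [cfg.codon_multipliers.get(truth.penultimate[g], 1.0) for g in truth.gene_ids]
        )
        mat[:, j_stop] *= cfg.stop_fold_change * mults
        mat[:, j_aug] *= cfg.utr3_fold_change
        mat[:, j_bg3] *= cfg.utr3_fold_change
        j_q = COMPONENTS.index("queued_80s")
        mat[:, j_q] *= cfg.queued_fold_change
        boosted[[j_stop, j_aug, j_bg3, j_q]] = True
    elif genotype == "rpl11b_d":
        j_start = COMPONENTS.index("start_peak")
        mat[:, j_start] *= cfg.start_fold_change
        boosted[j_start] = True
    elif genotype == "custom":
        pass  # caller edits cfg occupancies directly
    else:
        raise ValueError(f"unknown genotype {genotype!r}")

    boosted_mass = mat[:, boosted].sum()
    rest_mass = mat[:, ~boosted].sum()
    if boosted_mass < 1.0 and rest_mass > 0:
        # shrink unboosted components so totals match WT and the expected
        # rpm fold of each boosted component equals its configured fold
        mat[:, ~boosted] *= (1.0 - boosted_mass) / rest_mass
    else:
        logger.warning(
            "%s/%s: boosted occupancy mass %.3f >= 1; renormalizing whole mixture "
            "(realized rpm folds are smaller than configured; truth matrix is exact)",
            genotype, assay, boosted_mass,
        )
        mat /= mat.sum()
    return mat


def _draw_lengths(rng: np.random.Generator, cfg: SyntheticConfig, assay: str, k: int) -> np.ndarray:
    if assay == "ribo80":
        lo, hi = cfg.length_clip_80s
        lens = np.rint(rng.normal(cfg.length_mode_80s, cfg.length_spread_80s, size=k)).astype(int)
        return np.clip(lens, lo, hi)
    lo, hi = cfg.length_clip_40s
    lens = np.rint(rng.normal(cfg.length_mode_40s, cfg.length_spread_40s, size=k)).astype(int)
    lens = np.clip(lens, lo, hi)
    minor = rng.random(k) < cfg.minor21_fraction
    lens[minor] = 21
    return lens


def simulate_footprints(
    ann: GenomeAnnotation,
    truth: GroundTruth,
    cfg: SyntheticConfig,
    genotype: str = "wt",
    assay: str = "ssu40",
    n_reads: int | None = None,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Draw a footprint library from the genotype's occupancy mixture.

    Footprint 5' ends: stalled complexes at A-shift / S-shift (so the
    shifted P site lands on the anchor codon), queued 80S at
    S - queued_offset with +/-satellite jitter, 3'UTR AUG peaks at
    q - shift for planted AUGs q, and uniform backgrounds planted clear
    of the start/stop classification windows.  Lengths are drawn from
    the assay's length model independent of the 5' end (3'-end
    variability only); ORF background P-sites carry 3-nt periodicity.
    Records the sampling matrix in ``truth.probabilities``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.reads_per_sample if n_reads is None else n_reads
    shift = P_SITE_SHIFT[assay]
    mat = _genotype_matrix(ann, truth, cfg, genotype, assay)
    truth.probabilities[(genotype, assay)] = mat
    flat = mat.ravel() / mat.sum()
    counts = rng.multinomial(n, flat).reshape(mat.shape)

    sat = cfg.queued_satellite
    q_offsets = np.array([cfg.queued_offset, cfg.queued_offset - sat, cfg.queued_offset + sat])
    q_probs = np.array(
        [cfg.queued_main_weight, (1 - cfg.queued_main_weight) / 2, (1 - cfg.queued_main_weight) / 2]
    )

    genes_out: list[str] = []
    fives_out: list[np.ndarray] = []
    lens_out: list[np.ndarray] = []
    for i, gene in enumerate(truth.gene_ids):
        m = ann[gene]
        a, s, total = m.start_codon_pos, m.stop_start, m.length
        for j, comp in enumerate(COMPONENTS):
            k = int(counts[i, j])
            if k == 0:
                continue
            lens = _draw_lengths(rng, cfg, assay, k)
            if comp == "start_peak":
                five = np.full(k, a - shift)
            elif comp == "stop_peak":
                five = np.full(k, s - shift)
            elif comp == "queued_80s":
                five = s - q_offsets[rng.choice(3, size=k, p=q_probs)]
            elif comp == "utr3_aug":
                qs = np.array(truth.utr3_aug_positions[gene])
                five = qs[rng.integers(0, len(qs), size=k)] - shift
            elif comp == "utr5_bg":
                hi = a - 3 - lens  # whole footprint clear of the start window
                lens = np.minimum(lens, np.maximum(a - 3 - 1, 15))
                hi = a - 3 - lens
                five = rng.integers(0, np.maximum(hi, 1))
            elif comp == "orf_bg":
                lo = a + 7  # clear of the start window
                hi = s - 6 - lens  # clear of the stop window
                hi = np.maximum(hi, lo + 1)
                five = rng.integers(lo, hi)
                # impose 3-nt periodicity on the shifted P site
                p = five + shift
                frames = np.where(rng.random(k) < cfg.frame0_prob, 0, rng.integers(1, 3, size=k))
                delta = (a + frames - p) % 3
                five = five + delta
                five = np.where(five + lens > s - 6, five - 3, five)
                five = np.maximum(five, lo)
            elif comp == "utr3_bg":
                lo = s + 3
                hi = np.maximum(total - lens, lo + 1)
                five = rng.integers(lo, hi)
            else:  # pragma: no cover
                raise AssertionError(comp)
            lens = np.minimum(lens, total - five)
            genes_out.append(gene)
            fives_out.append(five.astype(np.int64))
            lens_out.append(lens.astype(np.int64))

    gene_col = np.concatenate(
        [np.full(len(f), g, dtype=object) for g, f in zip(genes_out, fives_out)]
    ) if genes_out else np.array([], dtype=object)
    df = pd.DataFrame(
        {
            "gene_id": gene_col,
            "five_prime": np.concatenate(fives_out) if fives_out else np.array([], dtype=np.int64),
            "length": np.concatenate(lens_out) if lens_out else np.array([], dtype=np.int64),
            "weight": 1,
        }
    )
    return df[READ_COLUMNS].astype({"five_prime": np.int64, "length": np.int64, "weight": np.int64})


# ---------------------------------------------------------------------------
# File emission: annotation bundle, BED-like alignments, FASTQ
# ---------------------------------------------------------------------------


def emit_annotation(
    ann: GenomeAnnotation, outdir: str | Path, intron_every: int = 7, seed: int = 0
) -> dict[str, Path]:
    """Write GFF3 + UTR table + genome FASTA for the synthetic transcriptome.

    Transcripts are laid head-to-tail on one synthetic chromosome with
    50-nt N spacers.  Every ``intron_every``-th gene gets its CDS split
    by a 60-nt intron (so splice-joining is exercised on re-load); the
    rest are single-exon, all on the plus strand.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom_parts: list[str] = []
    gff_lines = ["##gff-version 3"]
    utr_lines = ["gene_id\tutr5_len\tutr3_len\tutr5_intron"]
    cursor = 0

    def advance(seq: str) -> int:
        nonlocal cursor
        chrom_parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    for idx, gene_id in enumerate(ann.gene_ids):
        m = ann[gene_id]
        if idx > 0:
            advance("N" * 50)
        block_start = cursor  # 0-based genomic start of the transcript
        cds_start = block_start + m.utr5_len  # 0-based
        cds_end_nosplice = cds_start + m.cds_len
        with_intron = intron_every > 0 and idx % intron_every == intron_every - 1 and m.cds_len >= 60
        if with_intron:
            cds_seq = m.sequence[m.utr5_len : m.utr5_len + m.cds_len]
            split = 3 * (m.cds_len // 6)  # split near the middle, in frame
            intron = "GT" + "".join(BASES[rng.integers(0, 4, size=56)]) + "AG"
            genomic = (
                m.sequence[: m.utr5_len] + cds_seq[:split] + intron + cds_seq[split:]
                + m.sequence[m.utr5_len + m.cds_len :]
            )
            advance(genomic)
            seg1 = (cds_start + 1, cds_start + split)  # GFF 1-based inclusive
            seg2 = (cds_start + split + len(intron) + 1, cds_end_nosplice + len(intron))
            segments = [seg1, seg2]
            gene_end = block_start + len(genomic)
        else:
            advance(m.sequence)
            segments = [(cds_start + 1, cds_end_nosplice)]
            gene_end = block_start + m.length
        attrs = f"ID=gene:{gene_id}"
        gff_lines.append(
            f"chrSYN\ttcprof_sim\tgene\t{block_start + 1}\t{gene_end}\t.\t+\t.\t{attrs}"
        )
        for k, (s1, e1) in enumerate(segments):
            gff_lines.append(
                f"chrSYN\ttcprof_sim\tCDS\t{s1}\t{e1}\t.\t+\t{0 if k == 0 else '.'}\t"
                f"ID=cds:{gene_id}.{k};Parent=gene:{gene_id}"
            )
        utr_lines.append(f"{gene_id}\t{m.utr5_len}\t{m.utr3_len}\t0")

    chrom = "".join(chrom_parts)
    paths = {
        "gff": outdir / "annotation.gff3",
        "utr_table": outdir / "utr_lengths.tsv",
        "fasta": outdir / "genome.fa",
    }
    paths["gff"].write_text("\n".join(gff_lines) + "\n")
    paths["utr_table"].write_text("\n".join(utr_lines) + "\n")
    with open(paths["fasta"], "w") as fh:
        fh.write(">chrSYN\n")
        for i in range(0, len(chrom), 80):
            fh.write(chrom[i : i + 80] + "\n")
    return paths


DEFAULT_LINKER = LinkerSpec(
    linker_constant="CTGTAGGCACCATCAAT",
    barcode_map={"ATCGT": "wt", "AGCTA": "tma_dd", "CGTAA": "rpl11b_d", "TCAGC": "mrna"},
)


def _umi_strings(rng: np.random.Generator, k: int) -> list[str]:
    """k distinct 7-nt UMIs (sampled without replacement from 4^7)."""
    codes = rng.choice(4**7, size=k, replace=False)
    out = []
    for code in codes:
        umi = []
        for _ in range(7):
            umi.append("ACGT"[code % 4])
            code //= 4
        out.append("".join(umi))
    return out


def emit_fastq(
    reads_by_sample: dict[str, pd.DataFrame],
    ann: GenomeAnnotation,
    spec: LinkerSpec,
    path: str | Path,
    duplicate_rate: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    truth: GroundTruth | None = None,
) -> dict[str, dict[str, int]]:
    """Render footprints as linker/UMI/barcode-structured FASTQ reads.

    Each footprint becomes ``[2-nt RT UMI][insert][5-nt linker UMI]
    [barcode][linker constant]``.  UMIs are assigned distinct within each
    (sample, insert) group, so the unique-read truth counts are exact by
    construction; PCR duplicates are then planted by re-emitting existing
    reads until the duplicate fraction reaches ``duplicate_rate``.
    Returns (and records into ``truth``) per-sample unique and total
    counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    barcode_of = {sample: bc for bc, sample in spec.barcode_map.items()}
    entries: list[tuple[str, str, str]] = []  # (sample, full read seq, read id)
    unique_counts: dict[str, int] = {}
    for sample, df in reads_by_sample.items():
        if sample not in barcode_of:
            raise ValueError(f"sample {sample!r} has no barcode in the linker spec")
        bc = barcode_of[sample]
        inserts = [
            ann[g].sequence[fp : fp + ln]
            for g, fp, ln in zip(df["gene_id"], df["five_prime"], df["length"])
        ]
        unique_counts[sample] = len(inserts)
        order = pd.Series(inserts).groupby(inserts).groups
        seqs: list[str | None] = [None] * len(inserts)
        for insert, idx in order.items():
            for pos, umi in zip(idx, _umi_strings(rng, len(idx))):
                umi3, umi5 = umi[: spec.umi3_len], umi[spec.umi3_len :]
                seqs[pos] = umi5 + insert + umi3 + bc + spec.linker_constant
        for i, seq in enumerate(seqs):
            entries.append((sample, seq, f"{sample}_u{i}"))

    n_unique = len(entries)
    n_dup = int(round(duplicate_rate / (1 - duplicate_rate) * n_unique)) if duplicate_rate else 0
    dup_idx = rng.integers(0, n_unique, size=n_dup)
    all_entries = entries + [
        (entries[i][0], entries[i][1], f"{entries[i][2]}_dup{k}") for k, i in enumerate(dup_idx)
    ]
    perm = rng.permutation(len(all_entries))
    opener = __import__("gzip").open if str(path).endswith(".gz") else open
    total_counts: dict[str, int] = {s: 0 for s in reads_by_sample}
    with opener(path, "wt") as fh:
        for k in perm:
            sample, seq, rid = all_entries[k]
            total_counts[sample] += 1
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    result = {"unique": unique_counts, "total": total_counts}
    if truth is not None:
        truth.fastq_unique_counts = unique_counts
        truth.fastq_total_counts = total_counts
    return result
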