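"""Transcript coordinate system, sequences, and gene-exclusion rules.

Every downstream computation works in transcript space: position 0 is the
first nucleotide of the annotated 5'UTR, coordinates are 0-based and
intervals half-open.  The CDS includes the stop codon (yeast GFF
convention), so the first nucleotide of the stop codon sits at
``S = utr5_len + cds_len - 3`` and stop-relative offsets such as the
"-49 nt from the start of the 3'UTR" convention are ``pos - (S + 3)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


class AnnotationError(ValueError):
    """Raised for malformed annotation inputs (names the offending record)."""


@dataclass
class TranscriptModel:
    """One transcript in its own coordinate frame.

    ``sequence`` covers 5'UTR + spliced CDS + 3'UTR; ``cds_len`` includes
    the stop codon.  ``dubious``/``overlaps_other``/``utr5_intron`` carry
    the exclusion flags used by :func:`usable_genes`.
    """

    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: str
    dubious: bool = False
    overlaps_other: bool = False
    utr5_intron: bool = False

    def __post_init__(self) -> None:
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise AnnotationError(f"{self.gene_id}: negative UTR length")
        if self.cds_len < 6 or self.cds_len % 3 != 0:
            raise AnnotationError(
                f"{self.gene_id}: CDS length {self.cds_len} not a codon multiple >= 6"
            )
        expected = self.utr5_len + self.cds_len + self.utr3_len
        if len(self.sequence) != expected:
            raise AnnotationError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"utr5+cds+utr3 = {expected}"
            )
        stop = self.sequence[self.stop_start : self.stop_start + 3].upper()
        if stop not in STOP_CODONS:
            raise AnnotationError(f"{self.gene_id}: CDS does not end in a stop codon ({stop})")

    # -- coordinate helpers -------------------------------------------------

    @property
    def length(self) -> int:
        """Total transcript length in nt."""
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def start_codon_pos(self) -> int:
        """Position of the first nt of the start codon (A)."""
        return self.utr5_len

    @property
    def stop_start(self) -> int:
        """Position of the first nt of the stop codon (S)."""
        return self.utr5_len + self.cds_len - 3

    @property
    def utr3_start(self) -> int:
        """First nt of the 3'UTR (S + 3)."""
        return self.stop_start + 3

    def codon_at(self, position: int) -> str:
        """Codon at an in-frame codon index relative to the stop codon.

        ``position = -1`` is the penultimate codon (immediately 5' of the
        stop), ``-2`` the one before it, and so on; ``0`` is the stop codon
        itself.
        """
        first = self.stop_start + 3 * position
        if first < self.utr5_len or first + 3 > self.utr5_len + self.cds_len:
            raise IndexError(f"codon position {position} outside CDS of {self.gene_id}")
        return self.sequence[first : first + 3].upper()


class GenomeAnnotation:
    """Collection of :class:`TranscriptModel` keyed by unique gene id."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        for model in transcripts:
            self.add(model)

    def add(self, model: TranscriptModel) -> None:
        if model.gene_id in self.transcripts:
            raise AnnotationError(f"duplicate gene id {model.gene_id}")
        self.transcripts[model.gene_id] = model

    def __getitem__(self, gene_id: str) -> TranscriptModel:
        return self.transcripts[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.transcripts

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.transcripts)


def usable_genes(ann: GenomeAnnotation, purpose: str = "quantitation") -> list[str]:
    """Genes passing the exclusion rules, sorted.

    Dubious ORFs and transcripts overlapping other transcripts are always
    excluded.  Genes whose 5'UTR contains an intron are additionally
    excluded for ``purpose`` ``"quantitation"`` or ``"metacodon"`` (the
    position-average and gene-level quantitation analyses); ``purpose =
    "all"`` applies only the unconditional exclusions.
    """
    if purpose not in ("quantitation", "metacodon", "all"):
        raise ValueError(f"unknown purpose {purpose!r}")
    out = []
    for model in ann:
        if model.dubious or model.overlaps_other:
            continue
        if purpose != "all" and model.utr5_intron:
            continue
        out.append(model.gene_id)
    return sorted(out)


# ---------------------------------------------------------------------------
# Loading from GFF3 + UTR table + FASTA
# ---------------------------------------------------------------------------


def _read_utr_table(path: str | Path) -> dict[str, tuple[int, int, bool]]:
    """Parse the tab-separated UTR length table.

    Columns: gene_id, utr5_len, utr3_len, optional utr5_intron (0/1).  A
    header line starting with ``gene_id`` is allowed.
    """
    table: dict[str, tuple[int, int, bool]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 3:
                raise AnnotationError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            gene = fields[0]
            try:
                utr5, utr3 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed UTR length") from exc
            if utr5 < 0 or utr3 < 0:
                raise AnnotationError(f"{path}:{lineno}: negative UTR length")
            intron = bool(int(fields[3])) if len(fields) > 3 else False
            table[gene] = (utr5, utr3, intron)
    return table


def _gene_key(feature: gffutils.Feature) -> str:
    attrs = feature.attributes
    for key in ("Parent", "gene_id", "ID", "Name"):
        if key in attrs and attrs[key]:
            value = attrs[key][0]
            # strip common "gene:"/"cds:" prefixes
            return value.split(":", 1)[1] if ":" in value else value
    raise AnnotationError(f"CDS feature at line {feature.start} lacks Parent/ID attribute")


def _is_dubious(attrs: Mapping[str, list[str]]) -> bool:
    for key in ("orf_classification", "note", "Note"):
        for value in attrs.get(key, []):
            if "dubious" in value.lower():
                return True
    return False


def load_annotation(
    cds_file: str | Path,
    utr_table: str | Path,
    fasta: str | Path,
    overlap_span: str = "transcript",
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from GFF3 CDS, UTR table and FASTA.

    CDS segments of one gene are splice-joined in genomic order (reverse
    complemented for minus-strand genes); UTR sequence is taken as the
    genomic flank adjacent to the CDS ends, with lengths from ``utr_table``
    (genes absent from the table get zero-length UTRs).  CDSs whose length
    is not a codon multiple are skipped with a warning.  Transcript pairs
    whose genomic spans intersect, on either strand, get
    ``overlaps_other = True``; ``overlap_span`` chooses whether the span
    includes UTRs (``"transcript"``, default) or only the CDS (``"cds"``).
    """
    if overlap_span not in ("transcript", "cds"):
        raise ValueError("overlap_span must be 'transcript' or 'cds'")
    utrs = _read_utr_table(utr_table)
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    try:
        db = gffutils.create_db(
            str(cds_file),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted errors on bad input
        raise AnnotationError(f"{cds_file}: failed to parse GFF3 ({exc})") from exc

    genes: dict[str, dict] = {}
    gene_attrs: dict[str, Mapping] = {}
    for feat in db.features_of_type("gene"):
        gene_attrs[_gene_key(feat)] = feat.attributes
    for feat in db.features_of_type("CDS"):
        if feat.start > feat.end:
            raise AnnotationError(
                f"{cds_file}: CDS for {_gene_key(feat)} has start > end ({feat.start} > {feat.end})"
            )
        key = _gene_key(feat)
        entry = genes.setdefault(
            key, {"segments": [], "strand": feat.strand, "seqid": feat.seqid, "dubious": False}
        )
        if feat.seqid != entry["seqid"] or feat.strand != entry["strand"]:
            raise AnnotationError(f"{cds_file}: CDS segments of {key} disagree on seqid/strand")
        entry["segments"].append((feat.start, feat.end))
        entry["dubious"] = entry["dubious"] or _is_dubious(feat.attributes)

    for gene in utrs:
        if gene not in genes:
            raise AnnotationError(f"{utr_table}: gene {gene} absent from {cds_file}")

    models: list[TranscriptModel] = []
    spans: list[tuple[str, int, int, str]] = []
    for gene, entry in genes.items():
        segments = sorted(entry["segments"])
        strand = entry["strand"]
        seqid = entry["seqid"]
        if seqid not in genome:
            raise AnnotationError(f"{fasta}: missing sequence {seqid} needed by {gene}")
        chrom = genome[seqid]
        cds_seq = "".join(chrom[s - 1 : e] for s, e in segments)
        if strand == "-":
            cds_seq = str(Seq(cds_seq).reverse_complement())
        if len(cds_seq) < 6 or len(cds_seq) % 3 != 0:
            logger.warning(
                "skipping %s: CDS length %d not a codon multiple >= 6", gene, len(cds_seq)
            )
            continue
        utr5, utr3, intron = utrs.get(gene, (0, 0, False))
        first, last = segments[0][0], segments[-1][1]
        if strand == "-":
            up_start, up_end = last, last + utr5  # genomic coords of 5'UTR
            down_start, down_end = first - 1 - utr3, first - 1
            g_start, g_end = first - utr3, last + utr5
        else:
            up_start, up_end = first - 1 - utr5, first - 1
            down_start, down_end = last, last + utr3
            g_start, g_end = first - utr5, last + utr3
        if up_start < 0 or down_start < 0 or up_end > len(chrom) or down_end > len(chrom):
            raise AnnotationError(f"{gene}: UTR flank extends past the end of {seqid}")
        utr5_seq = chrom[up_start:up_end]
        utr3_seq = chrom[down_start:down_end]
        if strand == "-":
            utr5_seq = str(Seq(utr5_seq).reverse_complement())
            utr3_seq = str(Seq(utr3_seq).reverse_complement())
        dubious = entry["dubious"] or _is_dubious(gene_attrs.get(gene, {}))
        models.append(
            TranscriptModel(
                gene_id=gene,
                utr5_len=utr5,
                cds_len=len(cds_seq),
                utr3_len=utr3,
                sequence=utr5_seq + cds_seq + utr3_seq,
                dubious=dubious,
                utr5_intron=intron,
            )
        )
        if overlap_span == "cds":
            spans.append((seqid, first, last, gene))
        else:
            spans.append((seqid, g_start, g_end, gene))

    _flag_overlaps(models, spans)
    return GenomeAnnotation(models)


def _flag_overlaps(models: list[TranscriptModel], spans: list[tuple[str, int, int, str]]) -> None:
    """Mark genes whose genomic spans intersect (either strand), via sweep."""
    by_gene = {m.gene_id: m for m in models}
    ordered = sorted(spans)
    active: list[tuple[int, str]] = []  # (end, gene) on current seqid
    current_seqid = None
    for seqid, start, end, gene in ordered:
        if seqid != current_seqid:
            active = []
            current_seqid = seqid
        active = [(e, g) for e, g in active if e >= start]
        for _, other in active:
            if gene in by_gene:
                by_gene[gene].overlaps_other = True
            if other in by_gene:
                by_gene[other].overlaps_other = True
        active.append((end, gene))


# ---------------------------------------------------------------------------
# Consolidated cache (single tabular file for reuse)
# ---------------------------------------------------------------------------

_CACHE_HEADER = "gene_id\tutr5_len\tcds_len\tutr3_len\tdubious\toverlaps_other\tutr5_intron\tsequence"


def save_annotation_cache(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write the consolidated tab-separated annotation cache."""
    with open(path, "w") as fh:
        fh.write(_CACHE_HEADER + "\n")
        for gene_id in ann.gene_ids:
            m = ann[gene_id]
            fh.write(
                f"{m.gene_id}\t{m.utr5_len}\t{m.cds_len}\t{m.utr3_len}\t"
                f"{int(m.dubious)}\t{int(m.overlaps_other)}\t{int(m.utr5_intron)}\t{m.sequence}\n"
            )


def load_annotation_cache(path: str | Path) -> GenomeAnnotation:
    """Read an annotation cache written by :func:`save_annotation_cache`."""
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _CACHE_HEADER:
            raise AnnotationError(f"{path}:1: unexpected cache header")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 8:
                raise AnnotationError(f"{path}:{lineno}: expected 8 fields")
            models.append(
                TranscriptModel(
                    gene_id=fields[0],
                    utr5_len=int(fields[1]),
                    cds_len=int(fields[2]),
                    utr3_len=int(fields[3]),
                    sequence=fields[7],
                    dubious=bool(int(fields[4])),
                    overlaps_other=bool(int(fields[5])),
                    utr5_intron=bool(int(fields[6])),
                )
            )
    return GenomeAnnotation(models)
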