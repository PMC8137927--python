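"""Read-level preprocessing: linker trimming, demultiplexing, UMI dedup.

The modified library protocol ligates a 3' linker carrying a randomized
5-nt UMI followed by a 5-nt sample barcode and a constant region, and the
RT primer contributes a further randomized 2-nt UMI that ends up at the
5' end of the sequenced read.  A read therefore looks like::

    [2-nt RT UMI][insert][5-nt linker UMI][5-nt barcode][linker constant...]

Demultiplexing strips all of these, maps the barcode to a sample and
concatenates the two UMI segments (linker UMI first) into the 7-nt UMI
used for PCR-duplicate collapse.  Libraries made with the original
(UMI-less) protocol bypass deduplication; callers gate that on the
per-sample protocol flag.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import DEFAULTS

logger = logging.getLogger(__name__)


@dataclass
class RawRead:
    read_id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


@dataclass
class LinkerSpec:
    """Layout of the 3' linker and the RT-primer UMI."""

    linker_constant: str
    barcode_map: dict[str, str]
    umi3_len: int = 5
    barcode_len: int = 5
    umi5_len: int = 2

    def __post_init__(self) -> None:
        if self.umi3_len + self.umi5_len != 7:
            raise ValueError("UMI segments must total 7 nt (5 linker + 2 RT)")
        if len(set(self.barcode_map)) != len(self.barcode_map):
            raise ValueError("barcodes must be unique")
        for bc in self.barcode_map:
            if len(bc) != self.barcode_len:
                raise ValueError(f"barcode {bc} is not {self.barcode_len} nt")


@dataclass
class ProcessedRead:
    sample: str
    insert: str
    umi: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if len(self.umi) != 7:
            raise ValueError(f"{self.read_id}: UMI must be 7 nt, got {len(self.umi)}")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a FASTQ file (gzip transparently supported)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(read_id=title.split()[0], seq=seq.upper(), qual=qual)


def write_fastq(reads: Iterable[RawRead | ProcessedRead], path: str | Path) -> int:
    """Write reads (inserts, for processed reads) as FASTQ; returns count."""
    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for read in reads:
            seq = read.seq if isinstance(read, RawRead) else read.insert
            qual = (read.qual if isinstance(read, RawRead) else None) or "I" * len(seq)
            fh.write(f"@{read.read_id or f'read{n}'}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def demultiplex_trim(
    reads: Iterable[RawRead],
    spec: LinkerSpec,
    linker_mismatches: int = 0,
    barcode_mismatches: int = 0,
) -> tuple[list[ProcessedRead], Counter]:
    """Trim linkers, split by sample barcode, and assemble 7-nt UMIs.

    Returns the processed reads and a summary counter with per-sample
    totals plus ``no_linker``, ``too_short`` and ``unknown_barcode``
    drop categories.  The linker constant is located as an exact suffix
    (or exact internal match for reads sequenced past it); with
    ``linker_mismatches > 0`` a suffix-aligned match with at most that
    many mismatches is also accepted.
    """
    summary: Counter = Counter()
    out: list[ProcessedRead] = []
    constant = spec.linker_constant.upper()
    tail = spec.umi3_len + spec.barcode_len
    for read in reads:
        seq = read.seq
        idx = seq.rfind(constant)
        if idx < 0 and linker_mismatches > 0 and len(seq) >= len(constant):
            suffix = seq[-len(constant) :]
            if _hamming(suffix, constant) <= linker_mismatches:
                idx = len(seq) - len(constant)
        if idx < 0:
            # partial linker at the very end of the read (insert long
            # relative to read length): accept a constant prefix >= 6 nt
            for k in range(len(constant) - 1, 5, -1):
                if seq.endswith(constant[:k]):
                    idx = len(seq) - k
                    break
        if idx < 0:
            summary["no_linker"] += 1
            continue
        if idx < spec.umi5_len + tail:
            summary["too_short"] += 1
            continue
        barcode = seq[idx - spec.barcode_len : idx]
        umi3 = seq[idx - tail : idx - spec.barcode_len]
        umi5 = seq[: spec.umi5_len]
        insert = seq[spec.umi5_len : idx - tail]
        sample = spec.barcode_map.get(barcode)
        if sample is None and barcode_mismatches > 0:
            hits = [
                s for bc, s in spec.barcode_map.items()
                if _hamming(bc, barcode) <= barcode_mismatches
            ]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            summary["unknown_barcode"] += 1
            continue
        summary[sample] += 1
        out.append(ProcessedRead(sample=sample, insert=insert, umi=umi3 + umi5, read_id=read.read_id))
    return out, summary


def dedup_umi(reads: Iterable[ProcessedRead]) -> list[ProcessedRead]:
    """Collapse PCR duplicates: identical (sample, insert, 7-nt UMI).

    The first occurrence is kept, so output order is deterministic given
    input order, and the operation is idempotent.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[ProcessedRead] = []
    for read in reads:
        key = (read.sample, read.insert, read.umi)
        if key in seen:
            continue
        seen.add(key)
        out.append(read)
    return out


def size_select(reads: Iterable[ProcessedRead], assay: str) -> list[ProcessedRead]:
    """Keep reads whose insert length is within the assay's size range.

    Bounds are inclusive: 15-80 nt for 40S libraries, 25-34 nt for 80S.
    """
    lo, hi = DEFAULTS["size_range"][assay]
    kept, dropped = [], 0
    for read in reads:
        if lo <= len(read.insert) <= hi:
            kept.append(read)
        else:
            dropped += 1
    if dropped:
        logger.info("size_select(%s): dropped %d reads outside [%d, %d]", assay, dropped, lo, hi)
    return kept


def write_demux_report(summary: Counter, path: str | Path) -> None:
    """Tab-separated demultiplex summary (category, count)."""
    with open(path, "w") as fh:
        fh.write("category\tcount\n")
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
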