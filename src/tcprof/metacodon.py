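"""Position-average ("metacodon") occupancy around UTR motif occurrences.

Like a metagene, but anchored at every occurrence of a short motif (AUG,
or any stop codon) within 5'UTRs or 3'UTRs -- the readout used to detect
scanning 40S subunits initiating at upstream ORFs and unrecycled
subunits reinitiating in 3'UTRs.  Matching is a plain substring scan,
unconstrained by reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, STOP_CODONS, usable_genes
from .config import DEFAULTS
from .profiles import ProfileSet, gene_densities


def _scan(haystack: str, needle: str, offset: int) -> list[int]:
    """All (possibly overlapping) exact match starts, shifted by offset."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i + offset)
        i = haystack.find(needle, i + 1)
    return hits


def motif_positions(
    ann: GenomeAnnotation,
    motif: str,
    region: str,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Exact motif occurrences fully contained in the given UTR region.

    ``region`` is ``"UTR5"`` or ``"UTR3"``; matches are reported in all
    frames.  ``motif = "STOP"`` searches TAA/TAG/TGA jointly.  Genes with
    5'UTR introns (and dubious/overlapping genes) are excluded.
    """
    if region not in ("UTR5", "UTR3"):
        raise ValueError("region must be 'UTR5' or 'UTR3'")
    motifs = STOP_CODONS if motif.upper() == "STOP" else (motif.upper().replace("U", "T"),)
    if any(len(m) < 1 for m in motifs):
        raise ValueError("motif length must be >= 1")
    if genes is None:
        genes = usable_genes(ann, "metacodon")
    rows = []
    for gene in genes:
        m = ann[gene]
        if region == "UTR5":
            segment, offset = m.sequence[: m.utr5_len], 0
        else:
            segment, offset = m.sequence[m.utr3_start :], m.utr3_start
        for needle in motifs:
            for pos in _scan(segment.upper(), needle, offset):
                rows.append((gene, pos, region))
    df = pd.DataFrame(rows, columns=["gene_id", "position", "region"])
    return df.sort_values(["gene_id", "position"]).reset_index(drop=True)


@dataclass
class MetacodonResult:
    offsets: np.ndarray
    mean: np.ndarray
    n_occurrences: int
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean})


def metacodon_average(
    ps: ProfileSet,
    ann: GenomeAnnotation,
    occurrences: pd.DataFrame,
    window: tuple[int, int] = (50, 50),
    normalize_to_orf: bool = False,
    min_orf_rpkm: float | None = None,
    truncate_at_cds: bool = False,
) -> MetacodonResult:
    """Mean occupancy per offset across motif occurrences.

    Each occurrence contributes the rpm track of footprint 5' ends over
    offsets [-up, down) around the motif's first nt (occurrences whose
    window leaves the transcript are dropped; overlapping occurrences
    contribute independently).  Genes with no reads in the occurrence's
    UTR region are excluded.  With ``normalize_to_orf`` the track is
    divided by the gene's ORF density and genes below ``min_orf_rpkm``
    (default 5) are excluded.  ``truncate_at_cds`` zeroes window columns
    that extend out of the UTR into the CDS instead of keeping them.
    """
    min_orf = DEFAULTS["min_orf_rpkm"] if min_orf_rpkm is None else min_orf_rpkm
    up, down = window
    offsets = np.arange(-up, down)
    if occurrences.empty:
        raise ValueError("no motif occurrences supplied")
    orf_rpkm = None
    if normalize_to_orf:
        orf_rpkm = gene_densities(ps, ann, genes=sorted(occurrences["gene_id"].unique()))["orf_rpkm"]

    # per-gene, per-region read presence (unshifted 5' ends)
    def has_region_reads(gene: str, region: str) -> bool:
        m = ann[gene]
        track = ps.track(m)
        if region == "UTR5":
            return m.utr5_len > 0 and track[: m.utr5_len].sum() > 0
        return m.utr3_len > 0 and track[m.utr3_start :].sum() > 0

    presence: dict[tuple[str, str], bool] = {}
    total = np.zeros(len(offsets), dtype=float)
    n_used = 0
    used_genes: set[str] = set()
    for row in occurrences.sort_values(["gene_id", "position"]).itertuples(index=False):
        gene, pos, region = row.gene_id, int(row.position), row.region
        m = ann[gene]
        lo, hi = pos - up, pos + down
        if lo < 0 or hi > m.length:
            continue
        key = (gene, region)
        if key not in presence:
            presence[key] = has_region_reads(gene, region)
        if not presence[key]:
            continue
        if normalize_to_orf:
            rpkm = orf_rpkm.get(gene, np.nan)
            if not np.isfinite(rpkm) or rpkm < min_orf:
                continue
        values = ps.rpm_track(m)[lo:hi].copy()
        if normalize_to_orf:
            values /= rpkm
        if truncate_at_cds:
            span = np.arange(lo, hi)
            if region == "UTR5":
                values[span >= m.utr5_len] = 0.0
            else:
                values[span < m.utr3_start] = 0.0
        total += values
        n_used += 1
        used_genes.add(gene)
    if n_used == 0:
        raise ValueError("all motif occurrences were filtered out")
    return MetacodonResult(offsets=offsets, mean=total / n_used, n_occurrences=n_used, n_genes=len(used_genes))
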