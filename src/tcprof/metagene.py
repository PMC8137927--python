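"""Average occupancy profiles aligned at start or stop codons.

A metagene is the equal-weight mean, across genes, of per-gene rpm
tracks of footprint 5' ends (or 3' ends) at each offset relative to the
anchor codon's first nucleotide.  The 2-D variant resolves the average
by footprint length (15-80 nt), exposing whether length variation comes
from the 5' or the 3' end: with 3'-end variability, 5'-aligned matrices
show a vertical stripe and 3'-aligned matrices a diagonal.

Gene inclusion: a gene enters the average only when the flanking
features cover the window (100 nt of UTR and 300 nt of ORF for the
default 1-D windows; +/-100 nt of the feature of interest for 2-D).
Included genes with no reads in the window contribute zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import GenomeAnnotation, TranscriptModel, usable_genes
from .config import DEFAULTS
from .profiles import ProfileSet

LENGTH_SPAN = (15, 80)


@dataclass
class MetageneResult:
    anchor: str  # "start" | "stop"
    align_end: str  # "five_prime" | "three_prime"
    offsets: np.ndarray  # contiguous, relative to the anchor codon first nt
    mean_rpm: np.ndarray
    n_genes: int
    per_length: np.ndarray | None = None  # (n_lengths, n_offsets)
    lengths: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"offset": self.offsets, "mean_rpm": self.mean_rpm})

    def length_marginal(self) -> np.ndarray:
        """Sum of the per-length rows; equals the all-length 1-D trace."""
        if self.per_length is None:
            raise ValueError("no per-length matrix")
        return self.per_length.sum(axis=0)


def _included_genes(
    ann: GenomeAnnotation, anchor: str, upstream: int, downstream: int, genes: list[str]
) -> list[str]:
    out = []
    for gene in genes:
        m = ann[gene]
        if anchor == "start":
            ok = m.utr5_len >= upstream and m.cds_len >= downstream
        else:
            ok = m.cds_len >= upstream and m.utr3_len >= downstream
        if ok:
            out.append(gene)
    return out


def _aligned_positions(ps: ProfileSet, model: TranscriptModel, align_end: str, length_range):
    sub = ps.gene_reads(model.gene_id)
    pos = sub["five_prime"].to_numpy()
    lengths = sub["length"].to_numpy()
    weights = sub["weight"].to_numpy(dtype=float)
    if length_range is not None:
        lo, hi = length_range
        keep = (lengths >= lo) & (lengths <= hi)
        pos, lengths, weights = pos[keep], lengths[keep], weights[keep]
    if align_end == "three_prime":
        pos = pos + lengths - 1  # last protected nt, 0-based
    return pos, lengths, weights


def metagene_1d(
    ps: ProfileSet,
    ann: GenomeAnnotation,
    anchor: str,
    align_end: str = "five_prime",
    window: tuple[int, int] | None = None,
    length_range: tuple[int, int] | None = None,
    genes: list[str] | None = None,
) -> MetageneResult:
    """1-D metagene: mean rpm of aligned footprint ends per offset.

    ``window = (upstream, downstream)`` spans offsets [-upstream,
    downstream) relative to the anchor codon's first nt; defaults are
    (100, 300) at the start and (300, 100) at the stop, matching the
    gene-inclusion rule of 100 nt of UTR and 300 nt of ORF.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    if align_end not in ("five_prime", "three_prime"):
        raise ValueError("align_end must be 'five_prime' or 'three_prime'")
    if window is None:
        window = DEFAULTS["metagene_window_start" if anchor == "start" else "metagene_window_stop"]
    up, down = window
    if genes is None:
        genes = usable_genes(ann, "quantitation")
    included = _included_genes(ann, anchor, up, down, genes)
    if not included:
        raise ValueError("no gene passes the metagene inclusion rule")
    offsets = np.arange(-up, down)
    total = np.zeros(len(offsets), dtype=float)
    scale = 1e6 / ps.total_mapped
    for gene in included:
        m = ann[gene]
        c = m.start_codon_pos if anchor == "start" else m.stop_start
        pos, _, weights = _aligned_positions(ps, m, align_end, length_range)
        rel = pos - c + up
        ok = (rel >= 0) & (rel < len(offsets))
        np.add.at(total, rel[ok], weights[ok] * scale)
    return MetageneResult(
        anchor=anchor,
        align_end=align_end,
        offsets=offsets,
        mean_rpm=total / len(included),
        n_genes=len(included),
    )


def metagene_2d(
    ps: ProfileSet,
    ann: GenomeAnnotation,
    anchor: str,
    align_end: str = "five_prime",
    half_window: int | None = None,
    length_range: tuple[int, int] = LENGTH_SPAN,
    genes: list[str] | None = None,
) -> MetageneResult:
    """Length-resolved metagene over offsets [-half_window, half_window).

    Genes are included when both features flanking the anchor span at
    least ``half_window`` nt.  Rows cover each footprint length in
    ``length_range``; summing rows reproduces the 1-D trace computed with
    the same window and length range.
    """
    hw = DEFAULTS["metagene2d_halfwidth"] if half_window is None else half_window
    if genes is None:
        genes = usable_genes(ann, "quantitation")
    included = _included_genes(ann, anchor, hw, hw, genes)
    if not included:
        raise ValueError("no gene passes the metagene inclusion rule")
    lo, hi = length_range
    lengths_axis = np.arange(lo, hi + 1)
    offsets = np.arange(-hw, hw)
    matrix = np.zeros((len(lengths_axis), len(offsets)), dtype=float)
    scale = 1e6 / ps.total_mapped
    for gene in included:
        m = ann[gene]
        c = m.start_codon_pos if anchor == "start" else m.stop_start
        pos, lens, weights = _aligned_positions(ps, m, align_end, length_range)
        rel = pos - c + hw
        ok = (rel >= 0) & (rel < len(offsets))
        np.add.at(matrix, (lens[ok] - lo, rel[ok]), weights[ok] * scale)
    matrix /= len(included)
    return MetageneResult(
        anchor=anchor,
        align_end=align_end,
        offsets=offsets,
        mean_rpm=matrix.sum(axis=0),
        n_genes=len(included),
        per_length=matrix,
        lengths=lengths_axis,
    )


def write_metagene(result: MetageneResult, path) -> None:
    """Tabular output: (offset, mean_rpm), or a length x offset matrix."""
    import pandas as pd

    if result.per_length is None:
        result.to_frame().to_csv(path, sep="\t", index=False)
    else:
        df = pd.DataFrame(result.per_length, index=result.lengths, columns=result.offsets)
        df.rename_axis("length").to_csv(path, sep="\t")
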