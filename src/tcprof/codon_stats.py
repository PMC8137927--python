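"""Penultimate-codon dependence of 40S recycling: ratios and bootstrap.

For each gene the mutant/WT ratio of P-site-shifted stop-codon peak
heights (rpm-scaled, so library depth cancels) measures how much losing
the recycling factors inflates the stalled-40S peak.  Grouping genes by
the codon at a fixed position upstream of the stop (position -1 is the
penultimate codon, whose tRNA remains in the post-termination 40S P
site) and comparing each group's mean ratio to the transcriptome-wide
distribution via bootstrap resampling asks whether that codon modulates
the dependence on the recycling factors.

The null for a codon observed n times is the distribution of means of n
ratios drawn with replacement from the pooled all-gene ratios (20,000
draws by default); the two-sided percentile p-value uses an add-one
correction and significance is called at the 99% level per codon, with
no multiple-testing correction across codons (the per-codon confidence
interval is the reported quantity).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .config import DEFAULTS
from .profiles import PeakTable

logger = logging.getLogger(__name__)

RATIO_CODON_POSITIONS = tuple(range(-6, 0))


def _empty_stats() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "codon": pd.Series(dtype=str),
            "position": pd.Series(dtype=int),
            "n": pd.Series(dtype=int),
            "mean_ratio": pd.Series(dtype=float),
            "p_value": pd.Series(dtype=float),
            "significant": pd.Series(dtype=bool),
            "transcriptome_mean": pd.Series(dtype=float),
        }
    )


def peak_ratio_table(
    mut: PeakTable,
    wt: PeakTable,
    ann: GenomeAnnotation,
    min_wt_count: float | None = None,
    codon_positions: Sequence[int] = RATIO_CODON_POSITIONS,
) -> pd.DataFrame:
    """Per-gene mutant/WT stop-peak ratios with upstream codon context.

    Both tables must be anchored at the stop codon and quantitated with
    the same shift/window settings.  Ratios are ``mut_rpm / wt_rpm`` for
    genes whose WT peak count is at least ``min_wt_count`` (default 1;
    genes below it are omitted -- the ratio is undefined at zero).
    Columns ``codon_<p>`` hold the coding-strand, in-frame codon at each
    requested position relative to the stop codon.
    """
    if mut.anchor != wt.anchor:
        raise ValueError(f"anchor mismatch: {mut.anchor} vs {wt.anchor}")
    if mut.anchor != "stop":
        raise ValueError("peak ratio analysis is defined on stop-codon peaks")
    floor = DEFAULTS["min_wt_count"] if min_wt_count is None else min_wt_count
    joined = mut.table[["peak_count", "peak_rpm"]].join(
        wt.table[["peak_count", "peak_rpm"]], lsuffix="_mut", rsuffix="_wt", how="inner"
    )
    joined = joined[joined["peak_count_wt"] >= max(floor, 1e-12)]
    rows = []
    for gene, rec in joined.iterrows():
        model = ann[gene]
        codons = {f"codon_{p}": model.codon_at(p) for p in codon_positions}
        rows.append(
            {
                "gene_id": gene,
                "wt_peak": rec["peak_count_wt"],
                "mut_peak": rec["peak_count_mut"],
                "ratio": rec["peak_rpm_mut"] / rec["peak_rpm_wt"],
                **codons,
            }
        )
    return pd.DataFrame(rows)


def codon_bootstrap(
    records: pd.DataFrame,
    position: int = -1,
    min_n: int | None = None,
    n_boot: int | None = None,
    alpha: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bootstrap test for codon-dependent deviation of the mean ratio.

    For each codon c with at least ``min_n`` (default 10) occurrences,
    the observed mean ratio m_c is compared with ``n_boot`` (default
    20,000) means of n_c ratios drawn with replacement from the pooled
    all-gene ratio distribution.  The two-sided percentile p-value with
    add-one correction is ``(1 + #{|null - mu| >= |m_c - mu|}) /
    (n_boot + 1)`` with mu the pooled mean; ``significant`` is
    ``p < alpha`` (default 0.01, the 99% confidence level).
    Reproducible given ``seed``.
    """
    min_n = DEFAULTS["min_codon_n"] if min_n is None else min_n
    n_boot = DEFAULTS["n_boot"] if n_boot is None else n_boot
    alpha = DEFAULTS["alpha"] if alpha is None else alpha
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    col = f"codon_{position}"
    if col not in records.columns:
        raise ValueError(f"records lack column {col}")
    pooled = records["ratio"].to_numpy(dtype=float)
    mu = pooled.mean()
    sizes = records.groupby(col)["ratio"].agg(["count", "mean"])
    eligible = sizes[sizes["count"] >= min_n].sort_index()
    if eligible.empty:
        logger.warning("no codon at position %d reaches min_n=%d", position, min_n)
        return _empty_stats()
    rows = []
    for codon, rec in eligible.iterrows():
        n_c = int(rec["count"])
        m_c = float(rec["mean"])
        null_means = pooled[rng.integers(0, len(pooled), size=(n_boot, n_c))].mean(axis=1)
        exceed = int(np.sum(np.abs(null_means - mu) >= abs(m_c - mu)))
        p = (1 + exceed) / (n_boot + 1)
        rows.append((codon, position, n_c, m_c, p, p < alpha, mu))
    return pd.DataFrame(
        rows, columns=["codon", "position", "n", "mean_ratio", "p_value", "significant", "transcriptome_mean"]
    )


def position_sweep(
    records: pd.DataFrame,
    positions: Iterable[int] = RATIO_CODON_POSITIONS,
    min_n: int | None = None,
    n_boot: int | None = None,
    alpha: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run :func:`codon_bootstrap` independently at each codon position.

    Each position gets an independent, deterministic random stream
    spawned from ``seed``, so adding or removing positions does not
    perturb the others' results.
    """
    positions = list(positions)
    if not positions:
        return _empty_stats()
    streams = np.random.SeedSequence(seed).spawn(len(positions))
    frames = []
    for pos, ss in zip(positions, streams):
        frames.append(
            codon_bootstrap(
                records,
                position=pos,
                min_n=min_n,
                n_boot=n_boot,
                alpha=alpha,
                seed=np.random.default_rng(ss),
            )
        )
    return pd.concat(frames, ignore_index=True)


def significant_per_position(stats: pd.DataFrame) -> pd.Series:
    """Count of significant codons at each swept position."""
    if stats.empty:
        return pd.Series(dtype=int)
    return stats.groupby("position")["significant"].sum().astype(int)
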