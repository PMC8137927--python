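"""Thin plotting layer over metagene/metacodon results (matplotlib)."""

from __future__ import annotations

import numpy as np

from .metagene import MetageneResult
from .metacodon import MetacodonResult


def plot_metagene(result: MetageneResult, ax=None, label: str | None = None):
    """1-D trace of mean rpm vs offset from the anchor codon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(result.offsets, result.mean_rpm, lw=1.0, label=label)
    ax.axvline(0, color="0.7", lw=0.8, ls="--")
    ax.set_xlabel(f"offset from {result.anchor} codon (nt, {result.align_end} ends)")
    ax.set_ylabel("mean rpm")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_metagene_2d(result: MetageneResult, ax=None, log: bool = True):
    """Length-resolved heatmap (footprint length vs offset)."""
    import matplotlib.pyplot as plt

    if result.per_length is None:
        raise ValueError("result has no per-length matrix")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data = np.log1p(result.per_length) if log else result.per_length
    ax.imshow(
        data,
        aspect="auto",
        origin="lower",
        extent=(result.offsets[0], result.offsets[-1], result.lengths[0], result.lengths[-1]),
        cmap="viridis",
    )
    ax.set_xlabel(f"offset from {result.anchor} codon (nt, {result.align_end} ends)")
    ax.set_ylabel("footprint length (nt)")
    return ax


def plot_metacodon(result: MetacodonResult, ax=None, label: str | None = None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(result.offsets, result.mean, lw=1.0, label=label)
    ax.axvline(0, color="0.7", lw=0.8, ls="--")
    ax.set_xlabel("offset from motif (nt)")
    ax.set_ylabel("mean occupancy")
    if label:
        ax.legend(frameon=False)
    return ax
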