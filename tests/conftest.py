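"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tcprof import (
    GenomeAnnotation,
    SyntheticConfig,
    TranscriptModel,
    build_profiles,
    generate_transcriptome,
    simulate_footprints,
)


def make_model(
    gene_id: str = "TOY1",
    utr5: int = 50,
    cds: int = 300,
    utr3: int = 100,
    penultimate: str = "AAA",
    seed: int = 0,
) -> TranscriptModel:
    """Deterministic toy transcript with valid start/stop codons."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=utr5 + cds + utr3)
    seq[utr5 : utr5 + 3] = list("ATG")
    s = utr5 + cds - 3
    seq[s : s + 3] = list("TAA")
    seq[s - 3 : s] = list(penultimate)
    return TranscriptModel(gene_id=gene_id, utr5_len=utr5, cds_len=cds, utr3_len=utr3, sequence="".join(seq))


@pytest.fixture()
def toy_model() -> TranscriptModel:
    return make_model()


@pytest.fixture()
def toy_ann(toy_model) -> GenomeAnnotation:
    return GenomeAnnotation([toy_model])


@pytest.fixture(scope="session")
def small_world():
    """61-gene transcriptome with a WT 40S library of 3e4 reads."""
    cfg = SyntheticConfig(n_genes=61, reads_per_sample=30_000)
    ann, truth = generate_transcriptome(cfg, seed=7)
    reads = simulate_footprints(ann, truth, cfg, "wt", "ssu40", seed=8)
    ps = build_profiles(reads, ann, "wt", "ssu40")
    return cfg, ann, truth, ps
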