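# tcprof

Analysis of **small-subunit (40S) and conventional (80S) ribosome
profiling** data: where do scanning, initiating, terminating and
unrecycled ribosomal complexes sit on mRNAs, and how does that change
when translation factors are removed?

40S footprinting captures mRNA fragments protected by small ribosomal
subunits (48S pre-initiation complexes at start codons, post-termination
40S subunits at stop codons), complementing classical 80S profiling of
elongating ribosomes. `tcprof` implements the computational side of such
a study for budding yeast:

- **Read preprocessing** for the linker/UMI library chemistry: 3′-linker
  trimming, 5-nt sample-barcode demultiplexing, PCR-duplicate collapse on
  the combined 7-nt UMI (5 nt from the linker + 2 nt from the RT primer),
  and footprint size selection (15–80 nt for 40S, 25–34 nt for 80S).
- **Region classification**: each footprint is assigned to 5′UTR, start
  codon, ORF, stop codon or 3′UTR; a footprint maps to the start codon if
  it overlaps the 9-nt window centered on the AUG, and to the stop codon
  if it overlaps the 9-nt window ending with the stop codon.
- **P-site quantitation**: footprint 5′ ends are shifted by a fixed
  offset (+14 nt for 40S, +13 nt for 80S) to the ribosomal P site, and
  start/stop peaks are quantitated by summing shifted counts in the 5-nt
  window on the anchor codon. Gene-level densities (rpkm) trim 15 nt from
  each ORF end and extend 3′UTRs by 25 nt; ratio analyses require 5 rpkm
  in the ORF and 0.5 rpkm in the 3′UTR.
- **Metagene and metacodon averages**: 1-D and length-resolved 2-D
  average occupancy profiles aligned at start/stop codons by 5′ or 3′
  footprint ends, and position averages around every AUG (or stop codon)
  occurrence inside UTRs.
- **Recycling statistics**: per-gene mutant/WT stop-peak ratios and a
  bootstrap test for whether the codon at a fixed position upstream of
  the stop (the penultimate codon, position −1, whose tRNA stays in the
  post-termination 40S P site) shifts the mean ratio away from the
  transcriptome-wide mean. For a codon seen *n* times, the null is the
  distribution of means of *n* ratios resampled with replacement from the
  pooled ratios (20,000 draws); significance is called at the 99% level.
- **A synthetic-data generator** that produces transcriptomes and
  footprint libraries with recorded ground truth — stalled-40S peaks at
  start/stop codons, queued-80S peaks one footprint length behind a
  stalled complex (−49 nt from the 3′UTR start, satellites at −46/−52),
  planted 3′UTR AUGs and dORFs, 3′-end length variability, 3-nt ORF
  periodicity, and full linker/UMI read structure — so every stage is
  testable without external downloads.

## Worked example

Simulate a wild-type and a recycling-deficient (*tma*∆∆-like) 40S
library on a balanced 610-gene transcriptome in which genes ending in
…AAA-STOP carry twice the stop-peak fold change, then recover the
planted structure:

```python
import numpy as np
from tcprof import (SyntheticConfig, generate_transcriptome, simulate_footprints,
                    build_profiles, region_fractions, peak_height, peak_ratio_table,
                    codon_bootstrap, metagene_1d)

cfg = SyntheticConfig(n_genes=610, codon_multipliers={"AAA": 2.0})
ann, truth = generate_transcriptome(cfg, seed=0)
wt  = build_profiles(simulate_footprints(ann, truth, cfg, "wt",     "ssu40", n_reads=100_000, seed=1), ann, "wt", "ssu40")
mut = build_profiles(simulate_footprints(ann, truth, cfg, "tma_dd", "ssu40", n_reads=100_000, seed=2), ann, "tma_dd", "ssu40")

fractions, _ = region_fractions(wt, ann)
print("WT region fractions:", {r.value: round(float(f), 3) for r, f in fractions.items()})

mg = metagene_1d(mut, ann, anchor="stop")
print("stop metagene peak offset:", mg.offsets[np.argmax(mg.mean_rpm)], "nt")

ratios = peak_ratio_table(peak_height(mut, ann, "stop"), peak_height(wt, ann, "stop"), ann)
print(f"mean stop-peak ratio over {len(ratios)} genes: {ratios['ratio'].mean():.1f}")

stats = codon_bootstrap(ratios, position=-1, n_boot=2000, seed=3)
print(stats[stats.significant][["codon", "n", "mean_ratio", "p_value"]].to_string(index=False))
```

Output:

```
WT region fractions: {'UTR5': 0.089, 'START': 0.582, 'ORF': 0.239, 'STOP': 0.04, 'UTR3': 0.049}
stop metagene peak offset: -14 nt
mean stop-peak ratio over 610 genes: 25.2
codon  n  mean_ratio  p_value
  AAA 10   73.477143 0.000500
  GGG 10   42.510833 0.009995
```

Reading the output: the WT library is start-codon dominated, as expected
for 40S footprints. The mutant's stop-codon metagene peaks at offset
−14, the 5′-end position whose shifted P site is the stop codon — the
signature of an unrecycled 40S. The bootstrap flags the planted AAA
penultimate codon far above the transcriptome mean; GGG is a false
positive of the kind the per-codon 99% threshold permits (≈0.6 of 61
codons expected per run, since no multiple-testing correction is
applied — the per-codon confidence interval is the reported quantity).
The mean measured ratio (25.2) sits above the planted rpm fold (20)
because per-gene ratios with small WT denominators are biased upward
(E[1/W] > 1/E[W]); see `docs/methods.md`.

A YAML-driven CLI wraps the same stages
(`tcprof simulate|preprocess|quantify|metagene|metacodon|codonstats|report`);
see `tcprof --help`.

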