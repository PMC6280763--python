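# cageforge

Analysis toolkit for CAGE (cap analysis of gene expression) promoterome
data, built around the computational battery used to validate low-input
*carrier* CAGE protocols: CTSS-level TSS mapping, referent power-law
normalization, tag clustering with interquantile-width promoter-shape
metrics, library benchmarking against a reference, core-promoter sequence
analysis, SOM expression profiling, TSS-switch detection, and in-silico
design and digestion of selectively degradable carrier RNA. A synthetic-data
generator with full ground truth makes every stage testable offline.

## The problem and the models

CAGE sequences the 5′ ends of capped RNAs, so every uniquely mapped tag
marks a transcription start site at single-nucleotide resolution. The
pipeline reduces alignments to **CTSSs** — unique (chromosome, position,
strand) 5′-end locations with tag counts — after resolving the
template-free G added by reverse transcriptase and collapsing paired-end
PCR duplicates.

**Normalization.** CAGE counts follow an approximate power law: the
reverse-cumulative count N(≥x) is linear on log–log axes with slope −α.
Each library's fitted α is mapped onto a referent distribution
(α_ref = 1.25) totalling T = 10⁶ normalized tags:

    tpm_i = s · count_i^(α/α_ref),   s chosen so Σ tpm_i = 10⁶

**Promoter shape.** Nearby same-strand CTSSs are single-linkage clustered
(gap ≤ 20 bp) into tag clusters. Cluster width is summarized by the
interquantile width (IQ-width) between the positions holding the 10th and
90th percentile of cumulative cluster signal; clusters with IQ-width ≤ 3 bp
are *sharp* promoters (TATA-box at −30, pyrimidine–purine initiator,
single dominant CTSS), wider ones *broad* (CpG-island context, ~10.5-bp
WW-dinucleotide phasing downstream of the dominant CTSS from the +1
nucleosome).

**Benchmarking.** A query library is compared with a deep reference via
Pearson correlation of raw TPM over the CTSS union, ROC curves with
reference CTSSs/clusters as truth, dominant-CTSS distance distributions,
per-CTSS expression-ratio heatmaps in expression-quartile blocks, and a
permutation test for heatmap similarity.

**Carrier design.** Low-input libraries become possible when the scarce
sample is brought to standard mass (5 µg) with a degradable carrier RNA: a
housekeeping-gene-like backbone carrying alternating I-CeuI (27-bp) and
I-SceI (18-bp) homing-endonuclease sites, transcribed as a 386–1034 bp
template ladder and mixed as ~10% capped / 90% uncapped molecules. The
module models multi-round digestion (per-site survival (1−e)^r), spike-in
mass planning, and qPCR ΔCt estimation of leftover carrier.

## Worked example

```python
import numpy as np
from cageforge import synthetic as syn, clustering as cl, \
    normalization as nm, benchmark as bm, seqfeatures as sf

genome, truth = syn.generate_genome(n_promoters=500, sharp_fraction=0.5,
                                    chrom_length=1_000_000, seed=0)
parent = syn.simulate_library(truth, depth_tags=1_000_000, seed=0)
reference = nm.normalize(parent)
clusters = cl.cluster_ctss(reference)
sharp = [c for c in clusters if c.shape_class == "sharp"]
broad = [c for c in clusters if c.shape_class == "broad"]

tata = sf.scan_pwm(sharp, genome, sf.tata_pwm())
period = sf.ww_periodicity(broad, genome)

degraded = syn.simulate_degradation(parent, 0.05, pcr_cycles=10,
                                    pcr_efficiency=0.8, seed=0)
query = nm.normalize(degraded)
summary = bm.benchmark_summary(query, reference,
                               cl.cluster_ctss(query), clusters)
```

Output of this run:

```
CTSSs: 22583   tags: 1000000
fitted alpha: 0.749   normalized total: 1000000.0
tag clusters: 500  (sharp 250, broad 250)
median IQ-width: 9.5
TATA hits in sharp promoters: 100.0%
WW period in broad promoters: 10.50 bp (peak/median 8.2)
degraded-vs-parent: Pearson 0.976  AUC(ctss) 1.000  dominant within 10 bp: 99.8%
```

All 500 implanted promoters are recovered as tag clusters; the TATA PWM
scan finds the implanted element upstream of every sharp promoter; the
spectral estimate returns the implanted 10.5-bp nucleosome phasing; and a
library degraded to 5% of its material and PCR-reamplified still agrees
with its parent almost perfectly — the dominant TSS moves by more than
10 bp in only 0.2% of promoters.

A `cageforge` console script exposes the common shell tasks
(`cageforge simulate | normalize | cluster | subsample | benchmark |
carrier …`); run `cageforge --help`.

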