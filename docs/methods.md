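# Methods

This note records the models implemented in `cageforge`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the procedure was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## CTSS extraction and corrections

A CTSS is a unique (chromosome, 1-based position, strand) 5′-end location
of uniquely mapped CAGE tags; its count is the number of contributing
reads. On the plus strand the 5′ end is the leftmost aligned base, on the
minus strand the rightmost. "Uniquely mapped" has no universal aligner
convention, so uniqueness is a configurable mapping-quality threshold
(default MAPQ ≥ 20) or an explicit per-read flag.

Reverse transcriptase adds a template-free G opposite the cap. A leading G
that mismatches the genome is unambiguous and the 5′ end shifts one base
toward 3′. A leading G that matches the genome is ambiguous: it is shifted
with probability equal to the locally observed mismatched-G fraction at
that (chromosome, position, strand), drawn from a seeded RNG. The local
fraction is the site-wise maximum-likelihood estimate of the artifact rate;
the rule is stated qualitatively in the protocol literature without a
formula, so this operationalization is a package choice.

Paired-end duplicate collapse keys on (chromosome, 5′ position, strand,
mate 3′ end): with a random-hexamer RT primer the mate end is a random
anchor per molecule, so identical keys are PCR copies. Collapse is
idempotent and reports the kept fraction.

Internal coordinates are 1-based inclusive; BED exports are 0-based
half-open.

## Power-law normalization

For distinct count values x, N(≥x) is the number of CTSSs with count ≥ x.
The library slope α is −(OLS slope) of log₁₀N(≥x) on log₁₀x over distinct
counts in the fit range (default counts ∈ [10, 1000]); fitting one point
per distinct value avoids letting the huge singleton class dominate the
regression. Counts map onto the referent distribution (α_ref = 1.25,
T = 10⁶) via `tpm = s·count^(α/α_ref)` with s pinning the total at T. The
map is strictly increasing, so ranks are preserved exactly, and it
transforms the count law N(≥x) ∝ x^(−α) into N(≥tpm) ∝ tpm^(−α_ref) over
the fit range. α_ref, the fit range and T are declared defaults (the value
1.25 follows the normalization literature the protocol papers cite), all
configurable. Degenerate libraries (fewer than two distinct counts in
range) fall back to simple TPM (count·10⁶/total).

The distinct-value OLS estimator is biased low when the fit window's upper
reaches are sparsely occupied (observed distinct values skip empty counts,
flattening the tail) and when the window overlaps the distribution body
below the typical count. Slope-recovery tests therefore run at problem
sizes where [10, 1000] lies in a densely populated tail; with CTSS-level
data the check uses a sharp-only genome, since broad promoters split each
promoter's tags over many positions and reshape the CTSS-level tail
relative to the promoter-weight law.

## Tag clusters and promoter shape

Single-linkage along each (chromosome, strand): CTSSs below `min_tpm`
(default 1 TPM) are dropped, then consecutive survivors with positional gap
≤ `max_gap` (default 20 bp, the convention of the established clustering
frameworks) join one cluster. Walking members 5′→3′ on the strand, the
q0.1 (q0.9) bound is the *first position* where cumulative expression
reaches 10% (90%) of the total — integer positions, no interpolation, so
results are exactly testable by hand arithmetic. IQ-width is the genomic
span between the two bounds (inclusive); sharp means IQ-width ≤ 3 bp.
Dominant-CTSS ties break toward the most 5′ position on the strand
(deterministic and strand-symmetric).

Consensus clusters merge strictly overlapping same-strand tag clusters
across samples into union regions (merge gap configurable, default 0);
per-sample expression is the sum of contributing cluster totals and the
per-sample dominant is the dominant of the sample's strongest contributing
cluster. The union rule is a declared choice; the literature reports
consensus clusters without defining the merge.

Genomic-location annotation assigns one category per cluster with
precedence promoter > 5′UTR > exon > intron > antisense > intergenic;
the promoter is a strand-oriented window around annotated transcript starts
(default −500..+100, configurable).

Subsampling draws tags without replacement (multivariate hypergeometric
across CTSS counts), the exact model of sequencing fewer molecules from the
same pool.

## Benchmarking

Correlation uses raw (non-log) TPM over the union of CTSS keys with
absences imputed as 0 — union semantics are the only choice that penalizes
missed positions. ROC curves rank query entities by descending TPM against
a truth set of reference CTSSs (TPM ≥ 1 by default) or reference cluster
regions; the curve is the rank-threshold step function with trapezoid AUC.
If every candidate is a truth entity the curve has no horizontal extent and
AUC is reported as 1.

Cluster pairing for dominant-TSS distances is *reciprocal* best overlap:
each cluster's candidate is the overlapping cluster sharing the most bases,
and a pair is kept only when the choice is mutual. This keeps one pair per
promoter even when a fragmented low-complexity query throws several
slivers onto one reference cluster.

Ratio heatmaps place one row per reference cluster, columns at
strand-oriented offsets from the reference dominant CTSS (default ±100);
cells hold log₂(query/reference) where both libraries detect the CTSS and
the reference TPM where the query missed it, with rows grouped into four
reference-expression quartile blocks.

The heatmap permutation test uses the Pearson correlation of column-mean
profiles as its statistic. The null permutes the entries *within each row*
of the second matrix: this destroys positional (column) alignment while
preserving per-row value distributions. (Permuting whole-row order would
leave column means — and hence the statistic — unchanged, so it cannot
serve as a null for this statistic.) p = (1 + #{null ≥ observed})/(1 + n).

## Sequence features

All windows are strand-oriented; minus-strand sequence is
reverse-complemented before counting, which makes every output invariant
under reverse-complementing the genome and flipping strands.

The PWM is a log₂-odds matrix (pseudocount 1, uniform background by
default). The default hit threshold is 80% of the achievable score range,
min + 0.8·(max − min) — the common reading of an "80th percentile match";
an empirical mode thresholding at the 80th percentile of a background
score sample is also available, since the phrase is ambiguous. The bundled
TATA matrix is a JASPAR-style TBP count matrix. The TATA search window
constrains window starts to offsets −35..−25 from the dominant CTSS,
bracketing the canonical −30 placement. Windows containing N are skipped.

WW periodicity averages the WW (AA/AT/TA/TT) indicator over offsets
+1..+150 downstream of the dominant CTSS, removes the linear trend, and
reports the period with maximal power on a fine direct-DFT grid over
5–20 bp. Peak *significance* is judged separately on a Welch
segment-averaged spectrum (64-sample segments, 75% overlap): a raw
periodogram bin has exponential sampling noise, so its band maximum
routinely reaches 4–9× the band median even for white noise, while segment
averaging shrinks per-bin variance enough that a 3×-median threshold
separates phased from unphased input. The negative control realigns each
cluster on a randomly chosen member CTSS, destroying phase coherence.

Interval/coverage overlays report, separately for sharp and broad
clusters, the fraction whose ±flank window intersects a BED track and the
strand-oriented average coverage profile.

## Expression profiling and switching

Expression matrices hold log₁₀(TPM+1) over consensus clusters passing a
minimum-expression filter, row-z-scored by default so profile shape rather
than absolute level drives the classes. SOM classes come from a seeded
batch self-organizing map on a 4×2 grid (eight classes, mirroring common
practice for two-sample profiling); nodes initialize at sampled data rows
and each epoch moves them to Gaussian-neighborhood-weighted means with the
radius shrinking from half the grid diagonal to 0.5. Training is
deterministic given the seed. No SOM implementation ships with the
scientific stack targeted here, so the (small) algorithm is implemented
directly.

A TSS-switching event is a consensus region where both samples reach
`min_tpm` (default 5 TPM) and the dominant CTSSs lie at least
`min_distance` (default 10 bp) apart. These thresholds are a declared
operationalization; published switching counts on real data are not an
implementation target.

## Carrier design and accounting

Recognition motifs are the enzyme-catalog canonical sites — I-SceI
TAGGGATAACAGGGTAAT (18 bp), I-CeuI TAACTATAACGGTCCTAAGGTAGCGAA (27 bp).
Sites are embedded alternately (spacing default 120 bp) into a
deterministic synthetic housekeeping-like coding backbone (ATG start, no
in-frame stops, moderate GC); the design must stay within 5 percentage
points of the backbone GC. The template ladder prepends the canonical
T7 promoter plus 5 random bases and appends 6 random 3′ bases, one
template per requested length (default ladder spans 386–1034 bp, ten
steps). Digestion is modeled as independent per-site, per-round cuts:
cut probability 1 − (1−e)^r, intact fraction (1−e)^(r·s) for s sites,
with a Monte-Carlo fragment-length simulation alongside the closed form.
Spike-in planning is mass conservation to the 5-µg protocol total; the
carrier mix draws lengths uniformly over the ladder and caps molecules
with probability 0.10. The qPCR model converts a ΔCt between whole-library
and carrier-specific amplicons into a molar fraction E^(−ΔCt) assuming
perfect doubling (E = 2, configurable); real amplicon efficiencies would
modify this.

## Synthetic data: what it emulates and what it does not

The generator places non-overlapping promoters (margin 500 bp) on an
i.i.d. background of GC 0.40. Sharp promoters receive the TATA PWM
consensus starting at −31 and a tag profile with 90% of mass on the
dominant CTSS; broad promoters receive a GC 0.60 island (±300 bp), WW
dinucleotides implanted with probability 0.9 at multiples of 10.5 bp over
+1..+150, and a tag profile mixing a discretized Gaussian (σ drawn from
5–30 bp) with a 25% mass boost at the dominant CTSS — the boost keeps the
dominant identifiable while the cluster stays broad. Every promoter gets
an initiator dinucleotide across [−1,+1] drawn from canonical usage
(CA/TG/TA preferred, with G-starting initiators present so capture-bias
simulations have signal to act on). Expression weights are Pareto with
reverse-cumulative slope 1.25.

Degradation: optional 5′-G capture bias (non-G tags survive with relative
probability 1−g), hypergeometric subsampling to a material fraction, and
optional PCR as a per-molecule branching process (per-cycle duplication
probability = efficiency) with multinomial resequencing back to the
original depth — reproducing duplicate-inflated, artificially sharp
low-complexity libraries. Carrier contamination appends uniform-position
tags on a dedicated contig at a chosen leftover fraction with exact origin
flags.

Two-condition experiments mark disjoint promoter subsets A-specific,
B-specific (10-fold expression fold change) or switching. Switching
promoters emit a 70/30 bimodal profile over two dominant positions
(default 30 bp apart, near published median switch distances) with the
major mode flipping between conditions; the bimodal bridge keeps the
region contiguous under the default clustering gap, which a hard jump
between two isolated sharp peaks would not be.

Not emulated: transcript-level RNA-seq structure, sequencing errors,
mappability, chromatin-driven covariation between promoters, and real
inter-promoter spacing. Passing tests therefore demonstrate correctness of
the *computations* under the stated generative assumptions, not protocol
performance on real tissue.

## Problem sizes and determinism

The test suite runs the full battery at reduced but non-trivial scale —
end-to-end benchmarking uses 500 promoters at 10⁶ tags with 5% degradation;
switch/SOM recovery uses 300 promoters, 20 implanted switches and 20
seeded SOM runs; periodicity uses 500 broad promoters — sizes at which the
recovery statistics are stable across seeds while the whole suite stays
fast. All stochastic steps take explicit seeds and are bit-reproducible.
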