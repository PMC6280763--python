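"""Synthetic genomes and CAGE libraries with full ground truth.

Every pipeline stage can be exercised offline against data whose truth is
known exactly.  The generator emits:

* a genome whose promoters follow the two canonical architectures — *sharp*
  (TATA-box at -30, pyrimidine-purine initiator, single dominant CTSS) and
  *broad* (GC-rich island, multi-CTSS signal, WW dinucleotides phased every
  ~10.5 bp downstream of the dominant TSS, mimicking the +1 nucleosome);
* CAGE libraries with power-law-distributed promoter expression and
  multinomial per-promoter tag placement;
* degraded libraries (subsampling + PCR duplication + optional 5'-G capture
  bias), carrier-contaminated libraries, and matched two-condition
  experiments with implanted TSS-switching events.

Defaults: background GC 0.40, broad-island GC 0.60, sharp promoters put 90%
of their tags on the dominant CTSS, broad spreads draw sigma from 5-30 bp,
and expression weights follow a power law of slope 1.25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import revcomp, rng_from_seed
from .ctss import make_ctss_table
from .seqfeatures import tata_pwm

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: initiator dinucleotide usage (strand-oriented [-1,+1]); CA/TG/TA dominate
INITIATOR_WEIGHTS = {
    "CA": 0.35, "TG": 0.20, "TA": 0.15, "CG": 0.10,
    "GG": 0.05, "AG": 0.05, "GA": 0.05, "CC": 0.05,
}

WW_PERIOD = 10.5
SHARP_OFFSETS = np.array([-1, 0, 1, 2])
SHARP_PROBS = np.array([0.04, 0.90, 0.04, 0.02])


@dataclass
class SyntheticTruth:
    """Generative record of a synthetic promoterome."""
    promoters: pd.DataFrame          # one row per promoter
    chrom: str
    chrom_length: int
    params: dict = field(default_factory=dict)
    switching_events: Optional[pd.DataFrame] = None

    @property
    def n_promoters(self) -> int:
        return len(self.promoters)

    def to_json(self, path) -> None:
        payload = {
            "chrom": self.chrom, "chrom_length": self.chrom_length,
            "params": self.params,
            "promoters": self.promoters.to_dict(orient="records"),
        }
        if self.switching_events is not None:
            payload["switching_events"] = self.switching_events.to_dict(
                orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _write_oriented(seq: np.ndarray, strand: str, dominant: int, offset: int,
                    base: str) -> None:
    """Set the base at a strand-oriented offset from a dominant position."""
    pos = dominant + offset if strand == "+" else dominant - offset
    if 1 <= pos <= len(seq):
        seq[pos - 1] = base if strand == "+" else COMPLEMENT[base]


def generate_genome(n_promoters: int = 500, sharp_fraction: float = 0.5,
                    chrom_length: int = 1_000_000, seed: Optional[int] = 0,
                    gc: float = 0.40, island_gc: float = 0.60,
                    island_halfwidth: int = 300, ww_prob: float = 0.9,
                    ww_region: Tuple[int, int] = (1, 150),
                    broad_sigma_range: Tuple[float, float] = (5.0, 30.0),
                    tata_offset: int = -31,
                    chrom: str = "chr1") -> Tuple[Dict[str, str], SyntheticTruth]:
    """Emit a synthetic genome and its promoter truth table.

    Promoters are placed in non-overlapping slots on a single chromosome
    with random strands.  Sharp promoters receive the TATA-box consensus
    starting at *tata_offset* (so the element sits around -30) and a sharp
    tag profile; broad promoters receive a GC-elevated island of
    ``+-island_halfwidth`` and WW dinucleotides implanted with probability
    *ww_prob* at offsets that are multiples of 10.5 bp within *ww_region*
    downstream of the dominant CTSS.  Every promoter gets an initiator
    dinucleotide across [-1,+1] drawn from the field's canonical usage.
    """
    rng = rng_from_seed(seed)
    margin = 500
    slot = chrom_length // n_promoters
    if slot < 2 * margin + 1:
        raise ValueError(
            f"overcrowded genome: {n_promoters} promoters need "
            f">= {n_promoters * (2 * margin + 1)} bp, have {chrom_length}")
    bases = np.array(list("ACGT"))
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_island = np.array([(1 - island_gc) / 2, island_gc / 2, island_gc / 2,
                         (1 - island_gc) / 2])
    seq = rng.choice(bases, size=chrom_length, p=p_bg)

    tata_seq = tata_pwm().consensus()
    inits = list(INITIATOR_WEIGHTS)
    init_p = np.array(list(INITIATOR_WEIGHTS.values()))
    init_p = init_p / init_p.sum()
    ww_steps = np.arange(1, int(ww_region[1] // WW_PERIOD) + 1)
    ww_offsets = np.round(WW_PERIOD * ww_steps).astype(int)
    ww_offsets = ww_offsets[(ww_offsets >= ww_region[0])
                            & (ww_offsets + 1 <= ww_region[1])]
    ww_dinucs = ["AA", "AT", "TA", "TT"]

    rows = []
    n_sharp = int(round(sharp_fraction * n_promoters))
    classes = np.array(["sharp"] * n_sharp
                       + ["broad"] * (n_promoters - n_sharp))
    rng.shuffle(classes)
    for i in range(n_promoters):
        lo = i * slot + margin
        hi = (i + 1) * slot - margin
        dom = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        klass = classes[i]
        initiator = inits[rng.choice(len(inits), p=init_p)]
        island = (np.nan, np.nan)
        spread = 1.0
        if klass == "broad":
            spread = float(rng.uniform(*broad_sigma_range))
            g_lo = dom - island_halfwidth
            g_hi = dom + island_halfwidth
            island = (g_lo, g_hi)
            seq[g_lo - 1:g_hi] = rng.choice(bases, size=g_hi - g_lo + 1,
                                            p=p_island)
            for off in ww_offsets:
                if rng.random() < ww_prob:
                    dn = ww_dinucs[rng.integers(len(ww_dinucs))]
                    _write_oriented(seq, strand, dom, off, dn[0])
                    _write_oriented(seq, strand, dom, off + 1, dn[1])
        else:
            for j, b in enumerate(tata_seq):
                _write_oriented(seq, strand, dom, tata_offset + j, b)
        _write_oriented(seq, strand, dom, -1, initiator[0])
        _write_oriented(seq, strand, dom, 0, initiator[1])
        rows.append({"chrom": chrom, "strand": strand, "dominant_pos": dom,
                     "promoter_class": klass, "spread": spread,
                     "initiator": initiator, "tata": klass == "sharp",
                     "island_start": island[0], "island_end": island[1]})
    truth = SyntheticTruth(
        promoters=pd.DataFrame(rows), chrom=chrom, chrom_length=chrom_length,
        params={"n_promoters": n_promoters, "sharp_fraction": sharp_fraction,
                "gc": gc, "island_gc": island_gc, "ww_prob": ww_prob,
                "ww_period": WW_PERIOD, "seed": seed,
                "broad_sigma_range": list(broad_sigma_range),
                "tata_offset": tata_offset})
    return {chrom: "".join(seq)}, truth


def _emission(klass: str, spread: float,
              dominant_boost: float = 0.25) -> Tuple[np.ndarray, np.ndarray]:
    """Per-promoter tag-placement distribution over strand-oriented offsets.

    Sharp promoters put 90% of tags on the dominant CTSS.  Broad promoters
    mix a discretized Gaussian of the promoter's spread with a mass boost at
    the dominant CTSS, so the dominant remains identifiable while the
    cluster stays wide.
    """
    if klass == "sharp":
        return SHARP_OFFSETS, SHARP_PROBS
    half = max(int(np.ceil(3 * spread)), 2)
    offsets = np.arange(-half, half + 1)
    gauss = np.exp(-0.5 * (offsets / spread) ** 2)
    gauss /= gauss.sum()
    probs = (1 - dominant_boost) * gauss
    probs[offsets == 0] += dominant_boost
    return offsets, probs / probs.sum()


def _draw_weights(rng: np.random.Generator, n: int, slope: float) -> np.ndarray:
    """Pareto expression weights with reverse-cumulative slope *slope*."""
    return rng.random(n) ** (-1.0 / slope)


def simulate_library(truth: SyntheticTruth, depth_tags: int = 10**6,
                     seed: Optional[int] = 0, slope: float = 1.25,
                     weights: Optional[np.ndarray] = None,
                     dominant_boost: float = 0.25) -> pd.DataFrame:
    """Sample a CTSS table from a synthetic promoterome.

    Promoter weights follow a power law of the configured slope (unless a
    weight vector is supplied); *depth_tags* tags are multinomially split
    over promoters and then over each promoter's emission profile.
    """
    n = truth.n_promoters
    if depth_tags < n:
        raise ValueError("depth must be at least the number of promoters")
    rng = rng_from_seed(seed)
    if weights is None:
        weights = _draw_weights(rng, n, slope)
    per_prom = rng.multinomial(depth_tags, weights / weights.sum())
    records = []
    for row, count in zip(truth.promoters.itertuples(index=False), per_prom):
        if count == 0:
            continue
        offsets, probs = _emission(row.promoter_class, row.spread,
                                   dominant_boost)
        draws = rng.multinomial(count, probs)
        sign = 1 if row.strand == "+" else -1
        for off, c in zip(offsets, draws):
            if c > 0:
                records.append((row.chrom, row.dominant_pos + sign * off,
                                row.strand, c))
    return make_ctss_table(records)


def simulate_degradation(table: pd.DataFrame, subsample_fraction: float,
                         pcr_cycles: int = 0, pcr_efficiency: float = 0.8,
                         g_bias: float = 0.0,
                         genome: Optional[Dict[str, str]] = None,
                         seed: Optional[int] = 0) -> pd.DataFrame:
    """Degrade a library: material loss, PCR duplication, 5'-G capture bias.

    Molecules are first thinned by the optional G-capture bias (non-G-
    initiating tags survive capture with probability ``1 - g_bias`` relative
    to G-initiating ones — the template-switching artifact), then subsampled
    without replacement to *subsample_fraction* of the original depth.  With
    ``pcr_cycles > 0`` each surviving molecule is amplified by a branching
    process (per-cycle duplication probability *pcr_efficiency*) and the
    amplified pool is resampled with replacement back to the original depth,
    reproducing duplicate-inflated low-complexity libraries.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if pcr_cycles < 0:
        raise ValueError("pcr_cycles must be >= 0")
    if not 0 <= pcr_efficiency <= 1:
        raise ValueError("pcr_efficiency must be in [0, 1]")
    if not 0 <= g_bias < 1:
        raise ValueError("g_bias must be in [0, 1)")
    rng = rng_from_seed(seed)
    counts = table["count"].to_numpy(dtype=np.int64).copy()
    depth0 = int(counts.sum())

    if g_bias > 0:
        if genome is None:
            raise ValueError("g_bias requires the genome to read +1 bases")
        keep_p = np.ones(len(table))
        for i, row in enumerate(table.itertuples(index=False)):
            base = genome[row.chrom][row.pos - 1].upper()
            if row.strand == "-":
                base = COMPLEMENT.get(base, base)
            if base != "G":
                keep_p[i] = 1.0 - g_bias
        counts = rng.binomial(counts, keep_p)

    n_target = int(round(subsample_fraction * counts.sum()))
    if subsample_fraction < 1:
        counts = rng.multivariate_hypergeometric(counts, n_target,
                                                 method="marginals")
    if pcr_cycles == 0:
        out = table.copy()
        out["count"] = counts
        return out[out["count"] > 0].reset_index(drop=True)

    # branching-process amplification per surviving molecule
    mol_ctss = np.repeat(np.arange(len(counts)), counts)
    copies = np.ones(len(mol_ctss), dtype=np.int64)
    for _ in range(pcr_cycles):
        copies += rng.binomial(copies, pcr_efficiency)
    # sequence the amplified pool back at the original depth
    draws = rng.multinomial(depth0, copies / copies.sum())
    new_counts = np.bincount(mol_ctss, weights=draws,
                             minlength=len(counts)).astype(np.int64)
    out = table.copy()
    out["count"] = new_counts
    return out[out["count"] > 0].reset_index(drop=True)


def spike_carrier(table: pd.DataFrame, design, leftover_fraction: float,
                  seed: Optional[int] = 0,
                  carrier_chrom: str = "carrier") -> pd.DataFrame:
    """Append carrier-derived tags so they make up *leftover_fraction* of all.

    Carrier tags start at uniform positions along the carrier sequence on a
    dedicated contig; an ``origin`` column ({'sample', 'carrier'}) partitions
    the table exactly, supporting mapping-rate accounting.
    """
    if not 0 <= leftover_fraction <= 1:
        raise ValueError("leftover_fraction must be in [0, 1]")
    out = table.copy()
    out["origin"] = "sample"
    if leftover_fraction == 0:
        return out
    rng = rng_from_seed(seed)
    n = int(table["count"].sum())
    m = int(round(n * leftover_fraction / (1 - leftover_fraction)))
    positions = rng.integers(1, len(design.sequence) + 1, size=m)
    carrier = make_ctss_table(pd.DataFrame({
        "chrom": carrier_chrom, "pos": positions, "strand": "+", "count": 1}))
    carrier["origin"] = "carrier"
    for col in out.columns:
        if col not in carrier.columns:
            carrier[col] = np.nan
    return pd.concat([out, carrier[out.columns]], ignore_index=True)


def generate_two_conditions(truth: SyntheticTruth, n_specific_a: int,
                            n_specific_b: int, n_switch: int,
                            switch_distance: int = 30,
                            depth_tags: int = 10**6,
                            specificity_fold: float = 10.0,
                            switch_sigma: float = 5.0,
                            seed: Optional[int] = 0,
                            slope: float = 1.25):
    """Two matched libraries with condition-specific and switching promoters.

    Disjoint promoter subsets are made A-specific, B-specific (expressed
    ``specificity_fold`` higher in their own condition) or switching (the
    dominant CTSS moves *switch_distance* bp 3' in condition B; tags follow
    a 70/30 bimodal profile over the two positions so the promoter region
    stays contiguous).  Remaining promoters are ubiquitous.  Returns
    ``(table_a, table_b, truth)`` with roles and switching events appended
    to the truth record.
    """
    if switch_distance < 1:
        raise ValueError("switch_distance must be >= 1")
    n = truth.n_promoters
    if n_specific_a + n_specific_b + n_switch > n:
        raise ValueError("role counts exceed available promoters")
    rng = rng_from_seed(seed)
    picks = rng.permutation(n)
    role = np.array(["ubiquitous"] * n, dtype=object)
    role[picks[:n_specific_a]] = "A"
    role[picks[n_specific_a:n_specific_a + n_specific_b]] = "B"
    sw = picks[n_specific_a + n_specific_b:
               n_specific_a + n_specific_b + n_switch]
    role[sw] = "switch"

    base_w = _draw_weights(rng, n, slope)
    w_a = base_w * np.where(role == "B", 1.0 / specificity_fold, 1.0)
    w_b = base_w * np.where(role == "A", 1.0 / specificity_fold, 1.0)

    proms = truth.promoters.copy()
    proms["role"] = role
    signs = np.where(proms["strand"] == "+", 1, -1)
    dom_a = proms["dominant_pos"].to_numpy()
    dom_b = dom_a.copy()
    dom_b[role == "switch"] = (dom_a + signs * switch_distance)[role == "switch"]

    def build(weights, dom_major, dom_minor, cond_seed):
        r = rng_from_seed(cond_seed)
        per_prom = r.multinomial(depth_tags, weights / weights.sum())
        records = []
        for i, (row, count) in enumerate(zip(proms.itertuples(index=False),
                                             per_prom)):
            if count == 0:
                continue
            sign = 1 if row.strand == "+" else -1
            if role[i] == "switch":
                # bimodal: 70% on this condition's dominant, 30% on the other
                off_major = (dom_major[i] - row.dominant_pos) * sign
                off_minor = (dom_minor[i] - row.dominant_pos) * sign
                offsets, probs = _bimodal(off_major, off_minor, switch_sigma)
            else:
                offsets, probs = _emission(row.promoter_class, row.spread)
            draws = r.multinomial(count, probs)
            for off, c in zip(offsets, draws):
                if c > 0:
                    records.append((row.chrom,
                                    row.dominant_pos + sign * off,
                                    row.strand, c))
        return make_ctss_table(records)

    seed_a = int(rng.integers(2**31 - 1))
    seed_b = int(rng.integers(2**31 - 1))
    table_a = build(w_a, dom_a, dom_b, seed_a)
    table_b = build(w_b, dom_b, dom_a, seed_b)

    events = proms.loc[role == "switch",
                       ["chrom", "strand", "dominant_pos"]].copy()
    events["dominant_a"] = dom_a[role == "switch"]
    events["dominant_b"] = dom_b[role == "switch"]
    events["distance"] = switch_distance
    out_truth = SyntheticTruth(promoters=proms, chrom=truth.chrom,
                               chrom_length=truth.chrom_length,
                               params={**truth.params,
                                       "switch_distance": switch_distance,
                                       "specificity_fold": specificity_fold,
                                       "two_condition_seed": seed},
                               switching_events=events.reset_index(drop=True))
    return table_a, table_b, out_truth


def _bimodal(off_major: int, off_minor: int, sigma: float,
             major_mass: float = 0.7, dominant_boost: float = 0.3):
    lo = min(off_major, off_minor) - int(np.ceil(3 * sigma))
    hi = max(off_major, off_minor) + int(np.ceil(3 * sigma))
    offsets = np.arange(lo, hi + 1)

    def comp(center):
        g = np.exp(-0.5 * ((offsets - center) / sigma) ** 2)
        g /= g.sum()
        p = (1 - dominant_boost) * g
        p[offsets == center] += dominant_boost
        return p

    probs = major_mass * comp(off_major) + (1 - major_mass) * comp(off_minor)
    return offsets, probs / probs.sum()


def write_genome_fasta(genome: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
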