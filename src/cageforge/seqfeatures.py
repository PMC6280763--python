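"""Sequence-level promoter-architecture analysis.

Sharp and broad promoter classes differ in their sequence grammar: sharp
promoters carry a TATA-box around -30 and a pyrimidine-purine initiator
(e.g. CA) across [-1,+1]; broad promoters sit in GC-rich (CpG-island)
context and show ~10.5-bp phasing of WW (AA/AT/TA/TT) dinucleotides
downstream of the dominant TSS, the signature of a rotationally positioned
+1 nucleosome.  This module measures all of these: initiator composition,
positional dinucleotide density matrices ordered by IQ-width, PWM scanning
with a score-range threshold, WW periodicity spectra, and overlap/coverage
overlays with external interval tracks.

All windows are strand-oriented: offsets are 5'->3' on the cluster strand
and minus-strand sequence is reverse-complemented before any counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as _signal

from ._util import IUPAC, GenomeLike, chrom_length, fetch, revcomp, rng_from_seed
from .clustering import TagCluster

BASES = "ACGT"


# ---------------------------------------------------------------------------
# PWM


@dataclass
class PWM:
    """Log-odds position weight matrix with a score-range hit threshold.

    A window is a hit when its score reaches
    ``min_score + threshold_fraction * (max_score - min_score)`` — i.e. an
    80th-percentile match of the achievable score range at the default
    threshold.  ``threshold_mode='empirical'`` instead places the cutoff at
    the *threshold_fraction* quantile of scores over a supplied background
    score sample.
    """
    matrix: np.ndarray                 # 4 x L log-odds, rows A,C,G,T
    threshold_fraction: float = 0.8
    threshold_mode: str = "range"
    background_scores: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 2:
            raise ValueError("PWM must be 4 x L with L >= 2")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def threshold(self) -> float:
        if self.threshold_mode == "range":
            return self.min_score + self.threshold_fraction * (
                self.max_score - self.min_score)
        if self.threshold_mode == "empirical":
            if self.background_scores is None:
                raise ValueError("empirical threshold needs background_scores")
            return float(np.quantile(self.background_scores,
                                     self.threshold_fraction))
        raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length mismatch")
        idx = [BASES.find(b) for b in window.upper()]
        if any(i < 0 for i in idx):
            raise ValueError(f"ambiguous base in window {window!r}")
        return float(sum(self.matrix[i, j] for j, i in enumerate(idx)))

    def scan(self, seq: str) -> np.ndarray:
        """Scores of every window of ``seq``; NaN where a window contains N."""
        seq = seq.upper()
        n = len(seq) - self.length + 1
        out = np.full(max(n, 0), np.nan)
        for i in range(max(n, 0)):
            win = seq[i:i + self.length]
            if all(b in BASES for b in win):
                out[i] = self.score(win)
        return out

    @classmethod
    def from_counts(cls, counts: np.ndarray, background=None,
                    pseudocount: float = 1.0, **kw) -> "PWM":
        """Log2-odds matrix from a 4 x L base-count matrix."""
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        freq = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        return cls(matrix=np.log2(freq / bg[:, None]), **kw)


# TATA-box (TBP binding preference) count matrix, JASPAR-style, rows A,C,G,T.
TATA_COUNTS = np.array([
    [61, 16, 352, 3, 354, 268, 360, 222, 155, 56, 83, 82, 82, 68, 77],
    [145, 46, 0, 10, 0, 0, 3, 2, 44, 135, 147, 127, 118, 107, 101],
    [152, 18, 2, 2, 5, 0, 20, 44, 157, 150, 128, 128, 128, 139, 140],
    [31, 309, 35, 374, 30, 121, 6, 121, 33, 48, 31, 52, 61, 75, 71],
])


def tata_pwm(threshold_fraction: float = 0.8) -> PWM:
    """The bundled TATA-box log-odds PWM (uniform background)."""
    return PWM.from_counts(TATA_COUNTS, threshold_fraction=threshold_fraction)


# ---------------------------------------------------------------------------
# oriented sequence windows


def oriented_window(genome: GenomeLike, chrom: str, center: int, strand: str,
                    lo: int, hi: int, pad: str = "N") -> str:
    """Sequence covering strand-oriented offsets lo..hi around *center*.

    Offset 0 is *center* itself; positive offsets run 5'->3' on *strand*.
    Out-of-chromosome positions are padded with ``N``.
    """
    length = chrom_length(genome, chrom)
    if strand == "+":
        g_lo, g_hi = center + lo, center + hi
    else:
        g_lo, g_hi = center - hi, center - lo
    s = max(g_lo, 1)
    e = min(g_hi, length)
    core = fetch(genome, chrom, s, e) if s <= e else ""
    seq = pad * (s - g_lo) + core + pad * (g_hi - e)
    return revcomp(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# composition


def ctss_composition(table: pd.DataFrame, genome: GenomeLike) -> dict:
    """Base frequency at +1 and dinucleotide frequency at [-1,+1] of CTSSs.

    The +1 base is the CTSS itself; the initiator dinucleotide spans the
    base immediately upstream and the CTSS, read 5'->3' on the CTSS strand.
    CTSSs at chromosome edges are excluded (their number is reported).
    Frequencies are over CTSS records (positions, not tag-weighted) and each
    table sums to 1.
    """
    base_counts: Dict[str, int] = {}
    dinuc_counts: Dict[str, int] = {}
    n_excluded = 0
    for row in table.itertuples(index=False):
        length = chrom_length(genome, row.chrom)
        if row.strand == "+":
            lo, hi = row.pos - 1, row.pos
        else:
            lo, hi = row.pos, row.pos + 1
        if lo < 1 or hi > length:
            n_excluded += 1
            continue
        seq = fetch(genome, row.chrom, lo, hi)
        if row.strand == "-":
            seq = revcomp(seq)
        if any(b not in BASES for b in seq):
            n_excluded += 1
            continue
        base_counts[seq[1]] = base_counts.get(seq[1], 0) + 1
        dinuc_counts[seq] = dinuc_counts.get(seq, 0) + 1
    def norm(d):
        total = sum(d.values())
        return pd.Series({k: v / total for k, v in sorted(d.items())}) \
            if total else pd.Series(dtype=float)
    return {"base_freq": norm(base_counts), "dinuc_freq": norm(dinuc_counts),
            "n_excluded": n_excluded}


def dominant_ctss_table(clusters: Sequence[TagCluster]) -> pd.DataFrame:
    """CTSS table of cluster dominant positions (for dominant-only composition)."""
    return pd.DataFrame({
        "chrom": [tc.chrom for tc in clusters],
        "pos": [tc.dominant_pos for tc in clusters],
        "strand": [tc.strand for tc in clusters],
        "count": 1,
        "tpm": [tc.dominant_tpm for tc in clusters],
    })


# ---------------------------------------------------------------------------
# positional dinucleotide density


def _pattern_indicator(seq: str, pattern: str) -> np.ndarray:
    p0, p1 = IUPAC[pattern[0].upper()], IUPAC[pattern[1].upper()]
    out = np.zeros(len(seq) - 1)
    for i in range(len(seq) - 1):
        out[i] = seq[i] in p0 and seq[i + 1] in p1
    return out


def dinuc_density_matrix(clusters: Sequence[TagCluster], genome: GenomeLike,
                         pattern: str = "TA", flank: int = 1000,
                         smooth: Optional[int] = 5) -> dict:
    """Positional dinucleotide-density matrix around dominant CTSSs.

    Rows are clusters sorted by IQ-width (sharpest on top); columns are
    strand-oriented offsets ``-flank..+flank``; entries indicate whether the
    dinucleotide starting at that offset matches the 2-letter IUPAC
    *pattern* (``WW`` = AA/AT/TA/TT, ``SS`` = CC/CG/GC/GG, ...).  Optional
    *smooth* applies a centered moving average along the position axis.
    Rows that needed padding beyond a chromosome edge are flagged.
    """
    if len(pattern) != 2 or any(c.upper() not in IUPAC for c in pattern):
        raise ValueError(f"pattern must be a 2-letter IUPAC pair, got {pattern!r}")
    ordered = sorted(clusters, key=lambda tc: tc.iq_width)
    mat = np.zeros((len(ordered), 2 * flank + 1))
    padded = np.zeros(len(ordered), dtype=bool)
    for i, tc in enumerate(ordered):
        seq = oriented_window(genome, tc.chrom, tc.dominant_pos, tc.strand,
                              -flank, flank + 1)
        padded[i] = "N" in seq
        mat[i] = _pattern_indicator(seq, pattern)
    if smooth:
        kernel = np.ones(smooth) / smooth
        mat = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, mat)
    return {"matrix": mat, "offsets": np.arange(-flank, flank + 1),
            "clusters": ordered,
            "iq_widths": np.array([tc.iq_width for tc in ordered]),
            "padded": padded}


# ---------------------------------------------------------------------------
# PWM scanning


def scan_pwm(clusters: Sequence[TagCluster], genome: GenomeLike, pwm: PWM,
             search_window: Tuple[int, int] = (-35, -25)) -> dict:
    """Scan a PWM across a strand-oriented window upstream of dominant CTSSs.

    *search_window* bounds the allowed window **start** offsets (default
    -35..-25, the canonical TATA-box placement).  A cluster is a hit when
    its best in-window score reaches the PWM threshold; windows containing
    N are skipped.  Returns per-cluster flags, best scores/offsets, and the
    aggregate hit percentage.
    """
    lo, hi = search_window
    if lo > hi:
        raise ValueError("search_window must be (lo, hi) with lo <= hi")
    thr = pwm.threshold
    hits = np.zeros(len(clusters), dtype=bool)
    best_scores = np.full(len(clusters), np.nan)
    best_offsets = np.full(len(clusters), np.nan)
    for i, tc in enumerate(clusters):
        seq = oriented_window(genome, tc.chrom, tc.dominant_pos, tc.strand,
                              lo, hi + pwm.length - 1)
        scores = pwm.scan(seq)
        if np.all(np.isnan(scores)):
            continue
        j = int(np.nanargmax(scores))
        best_scores[i] = scores[j]
        best_offsets[i] = lo + j
        hits[i] = scores[j] >= thr
    return {"hits": hits, "best_scores": best_scores,
            "best_offsets": best_offsets,
            "percent_with_hit": 100.0 * hits.mean() if len(clusters) else float("nan")}


# ---------------------------------------------------------------------------
# WW periodicity


@dataclass
class PeriodEstimate:
    period: float                 # dominant period, bp
    amplitude: float              # spectral power at the dominant period
    profile: np.ndarray           # average dinucleotide indicator by offset
    peak_to_median: float = float("nan")  # peak significance (see ww_periodicity)
    offsets: np.ndarray = field(default=None)
    spectrum_periods: np.ndarray = field(default=None)
    spectrum_power: np.ndarray = field(default=None)

    @property
    def significant(self) -> bool:
        """True when the band peak clears 3x the band-median power."""
        return self.peak_to_median > 3.0


def _spectrum(x: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Power of the detrended profile at each candidate period (direct DFT)."""
    t = np.arange(len(x))
    power = np.empty(len(periods))
    for i, p in enumerate(periods):
        z = np.exp(-2j * np.pi * t / p)
        power[i] = np.abs(np.dot(x, z)) ** 2 / len(x)
    return power


def _band_peak_to_median(x: np.ndarray, period_range: Tuple[float, float],
                         nperseg: int = 64) -> float:
    """Peak-to-median power ratio in the period band, Welch-averaged.

    A raw periodogram bin has exponential sampling noise, so its band
    maximum routinely exceeds several times the median even for white
    noise; averaging overlapping-segment periodograms shrinks the per-bin
    variance enough that a genuine phased component stands clear of the
    band while unstructured input stays near the median.
    """
    nperseg = min(nperseg, len(x))
    f, p = _signal.welch(x, nperseg=nperseg, noverlap=nperseg * 3 // 4,
                         detrend=False)
    with np.errstate(divide="ignore"):
        periods = np.where(f > 0, 1.0 / np.maximum(f, 1e-12), np.inf)
    band = p[(f > 0) & (periods >= period_range[0])
             & (periods <= period_range[1])]
    return float(band.max() / np.median(band))


def ww_periodicity(clusters: Sequence[TagCluster], genome: GenomeLike,
                   region: Tuple[int, int] = (1, 150), pattern: str = "WW",
                   period_range: Tuple[float, float] = (5.0, 20.0),
                   align: str = "dominant",
                   seed: Optional[int] = 0) -> PeriodEstimate:
    """Dominant periodicity of a dinucleotide profile downstream of the TSS.

    Averages the *pattern* indicator over strand-oriented offsets
    ``region[0]..region[1]`` from each cluster's dominant CTSS, removes the
    linear trend, and reports the period with maximal spectral power within
    *period_range*.  ``align='random'`` centers each cluster on a randomly
    chosen member CTSS instead — the negative control that destroys phase
    coherence.
    """
    lo, hi = region
    if hi - lo + 1 < 2 * period_range[1]:
        raise ValueError("region must cover at least two periods of interest")
    rng = rng_from_seed(seed)
    rows = []
    for tc in clusters:
        if align == "dominant":
            center = tc.dominant_pos
        elif align == "random":
            center = int(rng.choice(tc.positions))
        else:
            raise ValueError(f"unknown align mode {align!r}")
        seq = oriented_window(genome, tc.chrom, center, tc.strand, lo, hi + 1)
        rows.append(_pattern_indicator(seq, pattern))
    profile = np.mean(rows, axis=0)
    detrended = _signal.detrend(profile, type="linear")
    periods = np.arange(period_range[0], period_range[1] + 1e-9, 0.05)
    power = _spectrum(detrended, periods)
    k = int(np.argmax(power))
    return PeriodEstimate(period=float(periods[k]), amplitude=float(power[k]),
                          profile=profile,
                          peak_to_median=_band_peak_to_median(detrended,
                                                              period_range),
                          offsets=np.arange(lo, hi + 1),
                          spectrum_periods=periods, spectrum_power=power)


# ---------------------------------------------------------------------------
# interval / coverage overlays


def interval_overlay(clusters: Sequence[TagCluster], intervals: pd.DataFrame,
                     flank: int = 500,
                     value_col: Optional[str] = None) -> dict:
    """Overlap and average coverage of an interval track around promoters.

    *intervals* is BED-convention (chrom, start, end; 0-based half-open),
    optionally with a *value_col* (bedGraph-style signal, default indicator
    1).  For each cluster the strand-oriented window ``[-flank, +flank]``
    around the dominant CTSS is tested for intersection and its positional
    coverage accumulated.  Results are reported separately for sharp and
    broad clusters.
    """
    iv = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
    by_chrom = {c: g for c, g in iv.groupby("chrom")}
    offsets = np.arange(-flank, flank + 1)
    flags = np.zeros(len(clusters), dtype=bool)
    cov = np.zeros((len(clusters), len(offsets)))
    for i, tc in enumerate(clusters):
        grp = by_chrom.get(tc.chrom)
        if grp is None:
            continue
        sign = 1 if tc.strand == "+" else -1
        win_lo = tc.dominant_pos - flank
        win_hi = tc.dominant_pos + flank
        for row in grp.itertuples(index=False):
            s1, e1 = row.start + 1, row.end  # to 1-based inclusive
            if e1 < win_lo or s1 > win_hi:
                continue
            flags[i] = True
            value = getattr(row, value_col) if value_col else 1.0
            g = np.arange(max(s1, win_lo), min(e1, win_hi) + 1)
            cols = sign * (g - tc.dominant_pos) + flank
            cov[i, cols] += value
    sharp = np.array([tc.shape_class == "sharp" for tc in clusters])
    def summarize(mask):
        if mask.sum() == 0:
            return {"fraction": float("nan"), "profile": np.zeros(len(offsets))}
        return {"fraction": float(flags[mask].mean()),
                "profile": cov[mask].mean(axis=0)}
    return {"offsets": offsets, "flags": flags,
            "fraction": float(flags.mean()) if len(clusters) else float("nan"),
            "profile": cov.mean(axis=0) if len(clusters) else np.zeros(len(offsets)),
            "sharp": summarize(sharp), "broad": summarize(~sharp)}
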