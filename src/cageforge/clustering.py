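"""Tag clustering and promoter-shape summaries.

Nearby same-strand CTSSs arise from functionally equivalent transcripts and
are analyzed as one transcriptional unit, the *tag cluster*.  Clusters are
built by single-linkage along the chromosome (gap <= ``max_gap``), and each
is summarized by its interquantile width (IQ-width): the span between the
positions holding the 10th and 90th percentile of cumulative cluster signal,
robust to outlier CTSSs.  Clusters with IQ-width <= 3 bp are *sharp*
promoters (typically TATA-driven, single dominant TSS); wider clusters are
*broad* (typically CpG-island associated).

Also here: consensus clusters (cross-sample promoter regions), genomic
location annotation, and random subsampling used to emulate low-complexity
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import rng_from_seed, sort_ctss

SHARP_IQ_WIDTH_MAX = 3  # empirical sharp/broad boundary (bp)

LOCATION_CATEGORIES = ["promoter", "5UTR", "exon", "intron", "antisense",
                       "intergenic"]


@dataclass
class TagCluster:
    """A contiguous group of same-strand CTSSs with shape summaries."""
    chrom: str
    strand: str
    start: int
    end: int
    positions: np.ndarray        # member CTSS positions, ascending
    tpms: np.ndarray             # member expression, parallel to positions
    total_tpm: float = 0.0
    q_low_pos: int = 0           # genomic position of the q0.1 signal bound
    q_high_pos: int = 0          # genomic position of the q0.9 signal bound
    iq_width: int = 0
    dominant_pos: int = 0
    dominant_tpm: float = 0.0
    shape_class: str = ""

    def __len__(self):
        return len(self.positions)


def cluster_ctss(table: pd.DataFrame, max_gap: int = 20,
                 min_tpm: float = 1.0,
                 expression_col: Optional[str] = None) -> List[TagCluster]:
    """Single-linkage clustering of CTSSs along each (chrom, strand).

    CTSSs below *min_tpm* are dropped before linking; surviving consecutive
    CTSSs whose positional gap is <= *max_gap* join one cluster.  Strands are
    never merged.  Cluster summaries are filled via
    :func:`summarize_cluster`.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if expression_col is None:
        expression_col = "tpm" if "tpm" in table.columns else "count"
    if len(table) == 0:
        return []
    tab = sort_ctss(table[table[expression_col] >= min_tpm])
    clusters: List[TagCluster] = []
    for (chrom, strand), grp in tab.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        tpm = grp[expression_col].to_numpy(dtype=float)
        if len(pos) == 0:
            continue
        # breakpoints where the gap to the previous CTSS exceeds max_gap
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk_pos, chunk_tpm in zip(np.split(pos, breaks),
                                        np.split(tpm, breaks)):
            tc = TagCluster(chrom=chrom, strand=strand,
                            start=int(chunk_pos[0]), end=int(chunk_pos[-1]),
                            positions=chunk_pos, tpms=chunk_tpm)
            summarize_cluster(tc)
            clusters.append(tc)
    return clusters


def summarize_cluster(tc: TagCluster) -> TagCluster:
    """Fill quantile bounds, IQ-width, dominant CTSS and shape class.

    Members are walked 5'->3' on the cluster's strand; the q0.1 (q0.9) bound
    is the first position where cumulative expression reaches 10% (90%) of
    the cluster total — integer positions, no interpolation.  Dominant CTSS
    ties break toward the most 5' position.
    """
    if len(tc) == 0:
        raise ValueError("cannot summarize an empty cluster")
    order = slice(None) if tc.strand == "+" else slice(None, None, -1)
    pos = tc.positions[order]
    tpm = tc.tpms[order]
    cum = np.cumsum(tpm)
    total = cum[-1]
    q_low = pos[np.searchsorted(cum, 0.1 * total, side="left")]
    q_high = pos[np.searchsorted(cum, 0.9 * total, side="left")]
    tc.total_tpm = float(total)
    tc.q_low_pos = int(min(q_low, q_high))
    tc.q_high_pos = int(max(q_low, q_high))
    tc.iq_width = tc.q_high_pos - tc.q_low_pos + 1
    dom = np.flatnonzero(tpm == tpm.max())[0]  # first in 5'->3' walk
    tc.dominant_pos = int(pos[dom])
    tc.dominant_tpm = float(tpm[dom])
    tc.shape_class = "sharp" if tc.iq_width <= SHARP_IQ_WIDTH_MAX else "broad"
    return tc


def clusters_to_frame(clusters: Sequence[TagCluster]) -> pd.DataFrame:
    cols = ["chrom", "strand", "start", "end", "total_tpm", "q_low_pos",
            "q_high_pos", "iq_width", "dominant_pos", "dominant_tpm",
            "shape_class"]
    return pd.DataFrame([{c: getattr(tc, c) for c in cols} for tc in clusters])


def clusters_to_bed12(clusters: Sequence[TagCluster],
                      score_cap: float = 1000.0) -> pd.DataFrame:
    """BED12 view: thickStart/thickEnd mark the interquantile core."""
    max_tpm = max((tc.total_tpm for tc in clusters), default=1.0) or 1.0
    rows = []
    for tc in clusters:
        rows.append({
            "chrom": tc.chrom, "start": tc.start - 1, "end": tc.end,
            "name": f"dom={tc.dominant_pos}",
            "score": int(round(min(score_cap, score_cap * tc.total_tpm / max_tpm))),
            "strand": tc.strand,
            "thickStart": tc.q_low_pos - 1, "thickEnd": tc.q_high_pos,
            "itemRgb": "0,0,0", "blockCount": 1,
            "blockSizes": tc.end - tc.start + 1, "blockStarts": 0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# consensus clusters


def merge_consensus(sample_clusters: Dict[str, Sequence[TagCluster]],
                    max_gap: int = 0) -> pd.DataFrame:
    """Merge overlapping same-strand tag clusters across samples.

    Returns one row per consensus region with columns ``chrom, strand,
    start, end`` plus, per sample, ``tpm_<name>`` (sum of contributing
    cluster totals, 0 if the sample has no signal there) and
    ``dominant_<name>`` (dominant CTSS of the sample's strongest
    contributing cluster; NaN if absent).
    """
    if not sample_clusters:
        raise ValueError("need at least one sample")
    entries = []  # (chrom, strand, start, end, sample, cluster)
    for name, clusters in sample_clusters.items():
        for tc in clusters:
            entries.append((tc.chrom, tc.strand, tc.start, tc.end, name, tc))
    names = list(sample_clusters)
    rows = []
    by_key: Dict[Tuple[str, str], list] = {}
    for e in entries:
        by_key.setdefault((e[0], e[1]), []).append(e)
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda e: (e[2], e[3]))
        current: list = []
        cur_end = None
        for e in group:
            if current and e[2] > cur_end + max_gap:
                rows.append(_consensus_row(chrom, strand, current, names))
                current = []
                cur_end = None
            current.append(e)
            cur_end = e[3] if cur_end is None else max(cur_end, e[3])
        if current:
            rows.append(_consensus_row(chrom, strand, current, names))
    return pd.DataFrame(rows)


def _consensus_row(chrom, strand, members, names):
    row = {"chrom": chrom, "strand": strand,
           "start": min(e[2] for e in members),
           "end": max(e[3] for e in members)}
    for name in names:
        mine = [e[5] for e in members if e[4] == name]
        row[f"tpm_{name}"] = float(sum(tc.total_tpm for tc in mine))
        if mine:
            best = max(mine, key=lambda tc: (tc.total_tpm,
                                             -tc.dominant_pos if strand == "+"
                                             else tc.dominant_pos))
            row[f"dominant_{name}"] = best.dominant_pos
        else:
            row[f"dominant_{name}"] = np.nan
    return row


# ---------------------------------------------------------------------------
# genomic-location annotation


def annotate_location(clusters: Sequence[TagCluster],
                      transcripts: pd.DataFrame,
                      promoter_window: Tuple[int, int] = (-500, 100),
                      valid_chroms: Optional[Sequence[str]] = None) -> List[str]:
    """Assign each cluster one genomic-location category.

    *transcripts* needs columns ``chrom, start, end, strand`` (1-based
    transcript span) and may carry ``cds_start, cds_end`` (for 5'UTR calls)
    and ``exon_starts, exon_ends`` (lists; whole span treated as one exon if
    absent).  Precedence: promoter > 5'UTR > exon > intron > antisense >
    intergenic; the promoter is a strand-oriented window around the
    annotated transcript start (default -500..+100).
    """
    if valid_chroms is not None:
        known = set(valid_chroms)
        for tc in clusters:
            if tc.chrom not in known:
                raise ValueError(f"cluster chromosome {tc.chrom!r} absent "
                                 "from annotation assembly")
    by_chrom: Dict[str, list] = {}
    for _, t in transcripts.iterrows():
        by_chrom.setdefault(t["chrom"], []).append(t)
    up, down = promoter_window
    out = []
    for tc in clusters:
        cats = set()
        for t in by_chrom.get(tc.chrom, []):
            t_start, t_end, t_strand = int(t["start"]), int(t["end"]), t["strand"]
            tss = t_start if t_strand == "+" else t_end
            if t_strand == "+":
                prom = (tss + up, tss + down)
            else:
                prom = (tss - down, tss - up)
            same = t_strand == tc.strand
            if same and _overlaps(tc.start, tc.end, *prom):
                cats.add("promoter")
            if not _overlaps(tc.start, tc.end, t_start, t_end):
                continue
            if not same:
                cats.add("antisense")
                continue
            exons = _exon_list(t, t_start, t_end)
            in_exon = any(_overlaps(tc.start, tc.end, s, e) for s, e in exons)
            utr5 = _utr5_interval(t, t_start, t_end, t_strand)
            if utr5 and in_exon and _overlaps(tc.start, tc.end, *utr5):
                cats.add("5UTR")
            elif in_exon:
                cats.add("exon")
            else:
                cats.add("intron")
        out.append(next((c for c in LOCATION_CATEGORIES if c in cats),
                        "intergenic"))
    return out


def _overlaps(a1, a2, b1, b2):
    return a1 <= b2 and b1 <= a2


def _exon_list(t, t_start, t_end):
    if "exon_starts" in t.index and isinstance(t["exon_starts"], (list, tuple)):
        return list(zip(t["exon_starts"], t["exon_ends"]))
    return [(t_start, t_end)]


def _utr5_interval(t, t_start, t_end, strand):
    if "cds_start" not in t.index or pd.isna(t.get("cds_start")):
        return None
    cds_start, cds_end = int(t["cds_start"]), int(t["cds_end"])
    if strand == "+":
        return (t_start, cds_start - 1) if cds_start > t_start else None
    return (cds_end + 1, t_end) if cds_end < t_end else None


# ---------------------------------------------------------------------------
# subsampling


def subsample_library(table: pd.DataFrame, n_tags: Optional[int] = None,
                      fraction: Optional[float] = None,
                      seed: Optional[int] = 0) -> pd.DataFrame:
    """Draw tags without replacement (multivariate hypergeometric).

    Emulates a shallower sequencing of the same molecule population; CTSSs
    losing all their tags are dropped.
    """
    total = int(table["count"].sum())
    if n_tags is None:
        if fraction is None:
            raise ValueError("give n_tags or fraction")
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if fraction == 1:
            return table.copy()
        n_tags = int(round(fraction * total))
    if n_tags > total:
        raise ValueError(f"requested {n_tags} tags but library has {total}")
    rng = rng_from_seed(seed)
    counts = table["count"].to_numpy(dtype=np.int64)
    new = rng.multivariate_hypergeometric(counts, n_tags, method="marginals")
    out = table.copy()
    out["count"] = new
    out = out[out["count"] > 0].reset_index(drop=True)
    return out
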