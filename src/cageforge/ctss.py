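"""CTSS extraction and I/O.

A CAGE library is reduced to CTSSs (CAGE tag-supported TSSs): unique
(chromosome, position, strand) locations of aligned-tag 5' ends, each with a
raw tag count.  This module turns aligned reads into a CTSS table, applies
the two standard pre-processing corrections — removal of the template-free G
that reverse transcriptase adds opposite the cap, and collapse of paired-end
PCR duplicates — and reads/writes the tabular formats involved.

The in-memory CTSS table is a :class:`pandas.DataFrame` with columns
``chrom, pos, strand, count`` (and ``tpm`` after normalization), 1-based
positions, sorted by (chrom, pos, strand) with unique keys.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

from ._util import GenomeLike, check_strand, fetch, rng_from_seed, sort_ctss

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]

#: default mapping-quality threshold for "uniquely mapped"
DEFAULT_MIN_MAPQ = 20


def make_ctss_table(records: Union[pd.DataFrame, Iterable[tuple]]) -> pd.DataFrame:
    """Build a validated CTSS table from (chrom, pos, strand, count) records.

    Aggregates duplicate keys by summing counts, drops zero-count rows,
    validates strands and positivity, and sorts.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records), columns=CTSS_COLUMNS)
    missing = set(CTSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CTSS table missing columns: {sorted(missing)}")
    if len(df) == 0:
        return pd.DataFrame(columns=CTSS_COLUMNS).astype(
            {"pos": np.int64, "count": np.int64})
    check_strand(df["strand"])
    if (df["count"] < 0).any():
        raise ValueError("negative CTSS count")
    df = (df.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
            .sum())
    df = df[df["count"] > 0].astype({"pos": np.int64, "count": np.int64})
    return sort_ctss(df)


def extract_ctss(reads: pd.DataFrame, min_mapq: int = DEFAULT_MIN_MAPQ) -> pd.DataFrame:
    """Tally aligned-read 5' ends into a CTSS table.

    *reads* is a DataFrame with columns ``chrom, start, end, strand``
    (1-based inclusive alignment span) and optionally ``mapq`` and/or a
    boolean ``unique`` flag.  The 5' end is ``start`` on the plus strand and
    ``end`` on the minus strand.  Reads failing the uniqueness criterion
    (``unique`` False, or ``mapq`` below *min_mapq*) are excluded.
    """
    if len(reads) == 0:
        return make_ctss_table([])
    bad = ~reads["strand"].isin(["+", "-"])
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown strand {reads['strand'].iloc[idx]!r} at read index {idx}")
    keep = pd.Series(True, index=reads.index)
    if "unique" in reads.columns:
        keep &= reads["unique"].astype(bool)
    if "mapq" in reads.columns:
        keep &= reads["mapq"] >= min_mapq
    sel = reads.loc[keep]
    five_prime = np.where(sel["strand"] == "+", sel["start"], sel["end"])
    tall = pd.DataFrame({"chrom": sel["chrom"].to_numpy(),
                         "pos": five_prime,
                         "strand": sel["strand"].to_numpy(),
                         "count": 1})
    return make_ctss_table(tall)


def extract_ctss_alignments(path_or_alignments,
                            min_mapq: int = DEFAULT_MIN_MAPQ) -> pd.DataFrame:
    """Tally CTSSs from a SAM/BAM file or an iterable of pysam records.

    Secondary, supplementary and unmapped records are skipped; primary
    records must reach *min_mapq* to count as uniquely mapped.
    """
    import pysam

    if isinstance(path_or_alignments, (str, os.PathLike)):
        handle = pysam.AlignmentFile(os.fspath(path_or_alignments), "r")
        alignments = handle
    else:
        alignments = path_or_alignments
    rows = []
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        strand = "-" if aln.is_reverse else "+"
        pos = aln.reference_end if aln.is_reverse else aln.reference_start + 1
        rows.append((aln.reference_name, pos, strand, 1))
    return make_ctss_table(rows)


def correct_leading_g(reads: pd.DataFrame, genome: GenomeLike,
                      seed: Optional[int] = 0) -> pd.DataFrame:
    """Resolve the extra 5' G added by reverse transcriptase.

    *reads* carries per-read 5' ends: columns ``chrom, pos, strand,
    first_base``.  If the read's first base is a G that mismatches the genome
    it is an artifact of template-free addition and the 5' end is shifted one
    base toward 3' (pos+1 on ``+``, pos-1 on ``-``).  A matching first G is
    ambiguous: it is shifted with probability equal to the locally observed
    mismatched-G fraction at its (chrom, pos, strand) site, drawn from a
    seeded RNG.  Non-G first bases pass through unchanged.

    Returns a copy of *reads* with corrected ``pos``.
    """
    out = reads.copy().reset_index(drop=True)
    if len(out) == 0:
        return out
    check_strand(out["strand"])
    first = out["first_base"].str.upper().to_numpy()
    is_g = first == "G"
    if "genome_match" in out.columns:
        matches = out["genome_match"].astype(bool).to_numpy()
    else:
        matches = np.empty(len(out), dtype=bool)
        for i, row in out.iterrows():
            try:
                ref = fetch(genome, row["chrom"], row["pos"], row["pos"])
            except (IndexError, KeyError) as exc:
                raise IndexError(
                    f"read {i} at {row['chrom']}:{row['pos']} outside genome"
                ) from exc
            if row["strand"] == "-":
                ref = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(ref, ref)
            matches[i] = first[i] == ref

    shift = np.where(out["strand"].to_numpy() == "+", 1, -1)
    new_pos = out["pos"].to_numpy().copy()
    # mismatched leading G: unconditional shift
    mismatch_g = is_g & ~matches
    new_pos[mismatch_g] += shift[mismatch_g]
    # matching leading G: probabilistic shift by the local mismatch fraction
    rng = rng_from_seed(seed)
    key = out[["chrom", "pos", "strand"]].apply(tuple, axis=1)
    g_keys = key[is_g]
    if len(g_keys):
        frac = (pd.Series(mismatch_g[is_g], index=g_keys.to_numpy())
                  .groupby(level=0).mean())
        match_g_idx = np.flatnonzero(is_g & matches)
        for i in match_g_idx:
            p = frac[key.iloc[i]]
            if p > 0 and rng.random() < p:
                new_pos[i] += shift[i]
    out["pos"] = new_pos
    return out


def collapse_read_pair_duplicates(pairs: pd.DataFrame) -> Tuple[pd.DataFrame, float]:
    """Collapse PCR duplicates by identical read-pair coordinates.

    With a random-hexamer reverse-transcription primer, the mate 3' end is a
    random anchor, so two pairs sharing chrom, 5' position, strand *and* mate
    end are PCR copies of one molecule.  Keeps one pair per identical
    (chrom, five_prime_pos, strand, mate_end_pos) key.

    Returns ``(deduplicated, kept_fraction)``; *kept_fraction* is ``nan`` for
    empty input.
    """
    required = ["chrom", "five_prime_pos", "strand", "mate_end_pos"]
    missing = set(required) - set(pairs.columns)
    if missing:
        raise ValueError(f"unpaired records: missing columns {sorted(missing)}")
    if pairs[required].isna().any().any():
        raise ValueError("unpaired record: missing mate coordinate")
    if len(pairs) == 0:
        return pairs.copy(), float("nan")
    dedup = pairs.drop_duplicates(subset=required, keep="first").reset_index(drop=True)
    return dedup, len(dedup) / len(pairs)


def read_ctss(path) -> pd.DataFrame:
    """Read a CTSS TSV (chrom, pos, strand, count; no header)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated "
                                 f"fields, got {len(parts)}")
            chrom, pos, strand, count = parts[:4]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                pos_i, count_i = int(pos), int(count)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            if count_i < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos_i, strand, count_i))
    return make_ctss_table(rows)


def write_ctss(table: pd.DataFrame, path) -> None:
    table[CTSS_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def ctss_to_bed6(table: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a CTSS table (0-based half-open; score = count or tpm)."""
    score = table["tpm"] if "tpm" in table.columns else table["count"]
    return pd.DataFrame({
        "chrom": table["chrom"],
        "start": table["pos"] - 1,
        "end": table["pos"],
        "name": [f"ctss_{i}" for i in range(len(table))],
        "score": score,
        "strand": table["strand"],
    })
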