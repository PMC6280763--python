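"""Shared helpers: sequence access, complements, validation."""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

STRANDS = ("+", "-")

# IUPAC nucleotide codes -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

GenomeLike = Union[Mapping[str, str], "pyfaidx.Fasta"]  # noqa: F821


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def chrom_length(genome: GenomeLike, chrom: str) -> int:
    return len(genome[chrom])


def fetch(genome: GenomeLike, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start..end] (1-based inclusive) as an upper-case string.

    Works both on plain ``{chrom: sequence}`` mappings and on ``pyfaidx.Fasta``
    handles (whose records also support python slicing).
    """
    if start < 1 or end > chrom_length(genome, chrom):
        raise IndexError(
            f"window {chrom}:{start}-{end} outside chromosome bounds "
            f"(length {chrom_length(genome, chrom)})"
        )
    return str(genome[chrom][start - 1:end]).upper()


def fetch_oriented(genome: GenomeLike, chrom: str, start: int, end: int,
                   strand: str) -> str:
    """Like :func:`fetch` but returned 5'->3' on *strand*."""
    seq = fetch(genome, chrom, start, end)
    return revcomp(seq) if strand == "-" else seq


def check_strand(values) -> None:
    bad = set(np.asarray(values, dtype=object)) - set(STRANDS)
    if bad:
        raise ValueError(f"unknown strand value(s): {sorted(map(str, bad))}")


def sort_ctss(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(["chrom", "pos", "strand"], kind="mergesort",
                             ignore_index=True)


def rng_from_seed(seed) -> np.random.Generator:
    return np.random.default_rng(seed)
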