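"""Design and in-silico handling of selectively degradable carrier RNA.

Low-input cap-trapper CAGE becomes possible when the scarce sample is
brought to standard mass (5 ug) with a synthetic carrier RNA that can later
be removed.  The carrier is a housekeeping-gene-like backbone studded with
alternating recognition sites of two homing endonucleases — I-CeuI (27-bp
site) and I-SceI (18-bp site) — whose long sites essentially never occur in
a transcriptome, so digestion destroys only the carrier.  A primer ladder
produces carrier templates of graded lengths to mimic cellular RNA size
distribution, and the final mix combines ~10% capped with ~90% uncapped
molecules.

This module covers the dry half of that protocol: carrier design, template
ladders, a probabilistic multi-round digestion model, spike-in mass
arithmetic and a qPCR ddCt model of leftover carrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import revcomp, rng_from_seed

# Canonical homing-endonuclease recognition motifs (enzyme-catalog sequences).
I_SCEI_SITE = "TAGGGATAACAGGGTAAT"                 # 18 bp
I_CEUI_SITE = "TAACTATAACGGTCCTAAGGTAGCGAA"        # 27 bp
SITES = {"I-SceI": I_SCEI_SITE, "I-CeuI": I_CEUI_SITE}

T7_PROMOTER = "TAATACGACTCACTATAG"                 # canonical 18-base core

#: template-ladder lengths (bp) spanning the protocol's 386-1034 bp range
DEFAULT_LADDER_LENGTHS = tuple(range(386, 1035, 72))

DEFAULT_TOTAL_NG = 5000.0      # standard total RNA mass brought to RT (5 ug)
MIN_INPUT_NG = 5.0             # lower bound of usable sample input
DEFAULT_CAPPED_FRACTION = 0.10


def input_reduction_ratio(reference_ng: float = DEFAULT_TOTAL_NG,
                          low_input_ng: float = MIN_INPUT_NG) -> float:
    """Fold reduction in required RNA mass relative to the carrier-free
    reference protocol (5 ug reference vs the 5-ng lower input bound)."""
    if low_input_ng <= 0:
        raise ValueError("low_input_ng must be positive")
    return reference_ng / low_input_ng


def default_backbone(length: int = 1100, gc: float = 0.52,
                     seed: int = 20180001) -> str:
    """Synthetic housekeeping-gene-like backbone (deterministic).

    A stand-in coding sequence with mesophilic-bacterium-like codon
    statistics: an ATG start, no in-frame stops, and moderate GC — chosen so
    the backbone has no strong secondary-structure bias.  Fixed seed, so the
    default design is reproducible.
    """
    rng = rng_from_seed(seed)
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = ["ATG"]
    while sum(len(c) for c in codons) < length:
        c = "".join(rng.choice(list(bases), p=p, size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)[:length]


@dataclass
class CarrierDesign:
    sequence: str
    sites: List[Tuple[int, str]]          # (1-based motif start, enzyme)
    backbone_gc: float
    design_gc: float
    templates: list = field(default_factory=list)
    capped_fraction: float = DEFAULT_CAPPED_FRACTION


def gc_content(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def find_sites(sequence: str) -> List[Tuple[int, str]]:
    """Scan a sequence for both recognition motifs (1-based start positions)."""
    seq = sequence.upper()
    found = []
    for enzyme, motif in SITES.items():
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            found.append((i + 1, enzyme))
            start = i + 1
    return sorted(found)


def design_carrier(backbone: Optional[str] = None, n_sites: int = 8,
                   spacing: int = 120, offset: int = 30,
                   capped_fraction: float = DEFAULT_CAPPED_FRACTION) -> CarrierDesign:
    """Embed alternating I-CeuI / I-SceI sites into a backbone.

    Sites replace backbone bases (length is preserved) every *spacing* bp
    starting at *offset*, alternating enzymes so that digestion leaves no
    long identical repeats.  The result must stay within 5 percentage points
    of the backbone's GC content.
    """
    if backbone is None:
        backbone = default_backbone(max(offset + n_sites * spacing + 40, 1100))
    backbone = backbone.upper()
    max_motif = max(len(m) for m in SITES.values())
    if spacing < max_motif:
        raise ValueError(f"spacing {spacing} shorter than the longest motif "
                         f"({max_motif} bp)")
    enzymes = ["I-CeuI", "I-SceI"]
    seq = list(backbone)
    sites = []
    for k in range(n_sites):
        enzyme = enzymes[k % 2]
        motif = SITES[enzyme]
        start = offset + k * spacing          # 0-based insertion point
        if start + len(motif) > len(seq):
            raise ValueError(f"backbone too short for {n_sites} sites at "
                             f"spacing {spacing}")
        seq[start:start + len(motif)] = motif
        sites.append((start + 1, enzyme))
    out = "".join(seq)
    bg_gc, d_gc = gc_content(backbone), gc_content(out)
    if abs(d_gc - bg_gc) > 0.05:
        raise ValueError(f"site insertion moved GC content by "
                         f"{abs(d_gc - bg_gc):.3f} (> 0.05); use a longer "
                         "backbone or fewer sites")
    return CarrierDesign(sequence=out, sites=sites, backbone_gc=bg_gc,
                         design_gc=d_gc, capped_fraction=capped_fraction)


@dataclass
class Template:
    length: int
    sequence: str
    forward_primer: str
    reverse_primer: str


def build_template_ladder(design: CarrierDesign,
                          lengths: Sequence[int] = DEFAULT_LADDER_LENGTHS,
                          seed: Optional[int] = 0,
                          anchor_len: int = 20) -> List[Template]:
    """In-vitro-transcription template ladder for graded carrier lengths.

    The forward primer tail prepends the canonical T7 promoter plus 5 random
    bases; each reverse primer sets one total template length and appends 6
    random bases at the template's 3' end.  One template per requested
    length, each exactly that long.
    """
    rng = rng_from_seed(seed)
    bases = np.array(list("ACGT"))
    fwd_tail = T7_PROMOTER + "".join(rng.choice(bases, 5))
    min_len = len(fwd_tail) + anchor_len + 6
    templates = []
    for L in lengths:
        if L < min_len:
            raise ValueError(f"template length {L} below minimal amplicon "
                             f"({min_len} bp)")
        core_len = L - len(fwd_tail) - 6
        if core_len > len(design.sequence):
            raise ValueError(f"template length {L} exceeds carrier design "
                             f"({len(design.sequence)} bp core available)")
        core = design.sequence[:core_len]
        tail3 = "".join(rng.choice(bases, 6))
        seq = fwd_tail + core + tail3
        fwd_primer = fwd_tail + core[:anchor_len]
        rev_primer = revcomp(tail3) + revcomp(core[-anchor_len:])
        templates.append(Template(length=L, sequence=seq,
                                  forward_primer=fwd_primer,
                                  reverse_primer=rev_primer))
    design.templates = templates
    return templates


def in_silico_digest(sequence: str, efficiency: float, rounds: int = 2,
                     n_molecules: int = 10000,
                     seed: Optional[int] = 0) -> dict:
    """Monte-Carlo digestion of a carrier population.

    Each recognition site is cut independently per molecule with probability
    ``1 - (1 - e)**rounds`` (independent rounds); fragments are the maximal
    uncut intervals.  Returns the fragment-length distribution, the
    simulated intact fraction and the closed-form expectation
    ``(1 - e)**(rounds * n_sites)``.
    """
    if not 0 <= efficiency <= 1:
        raise ValueError("efficiency must be in [0, 1]")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    sites = find_sites(sequence)
    n = len(sequence)
    if not sites:
        warnings.warn("sequence carries no recognition sites; it is "
                      "undegradable", stacklevel=2)
        return {"fragment_lengths": np.array([n] * n_molecules),
                "intact_fraction": 1.0, "intact_fraction_expected": 1.0,
                "n_sites": 0}
    # cleave mid-motif; only relative fragment sizes matter for the model
    cut_points = np.array([pos - 1 + len(SITES[enz]) // 2
                           for pos, enz in sites])
    p_cut = 1.0 - (1.0 - efficiency) ** rounds
    rng = rng_from_seed(seed)
    cuts = rng.random((n_molecules, len(cut_points))) < p_cut
    fragments = []
    intact = 0
    bounds = np.concatenate([[0], cut_points, [n]])
    for row in cuts:
        if not row.any():
            intact += 1
            fragments.append(n)
            continue
        edges = np.concatenate([[0], cut_points[row], [n]])
        fragments.extend(np.diff(edges).tolist())
    return {"fragment_lengths": np.array(fragments),
            "intact_fraction": intact / n_molecules,
            "intact_fraction_expected": (1.0 - efficiency) ** (rounds * len(sites)),
            "n_sites": len(sites), "cut_probability": p_cut,
            "cut_points": bounds[1:-1]}


def plan_spike_in(sample_ng: float, total_ng: float = DEFAULT_TOTAL_NG) -> float:
    """Carrier mass (ng) to bring a sample to the protocol's total RNA mass."""
    if sample_ng <= 0:
        raise ValueError("sample mass must be positive")
    if sample_ng > total_ng:
        raise ValueError(f"sample mass {sample_ng} ng exceeds total "
                         f"{total_ng} ng")
    return total_ng - sample_ng


def compose_carrier_mix(design: Optional[CarrierDesign] = None,
                        capped_fraction: float = DEFAULT_CAPPED_FRACTION,
                        n_molecules: int = 100000,
                        lengths: Optional[Sequence[int]] = None,
                        seed: Optional[int] = 0) -> pd.DataFrame:
    """Simulate a carrier mix of varying length and capping state.

    Molecules take lengths uniformly over the template ladder and carry a
    cap with probability *capped_fraction* (protocol optimum: 10% capped /
    90% uncapped).  Returns a DataFrame with ``length`` and ``capped``.
    """
    if not 0 <= capped_fraction <= 1:
        raise ValueError("capped_fraction must be in [0, 1]")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if lengths is None:
        if design is not None and design.templates:
            lengths = [t.length for t in design.templates]
        else:
            lengths = DEFAULT_LADDER_LENGTHS
    rng = rng_from_seed(seed)
    return pd.DataFrame({
        "length": rng.choice(np.asarray(lengths), size=n_molecules),
        "capped": rng.random(n_molecules) < capped_fraction,
    })


def estimate_carrier_fraction_qpcr(ct_library: float, ct_carrier: float,
                                   amplification_base: float = 2.0) -> float:
    """Leftover carrier fraction from a qPCR ddCt comparison.

    With per-cycle amplification factor E, a carrier amplicon crossing
    threshold dCt cycles after the whole-library amplicon corresponds to a
    molar fraction ``E**(-dCt)``.  A negative dCt (fraction > 1) is allowed
    but flagged with a warning.
    """
    if amplification_base <= 1:
        raise ValueError("amplification base must exceed 1")
    if ct_library < 0 or ct_carrier < 0:
        raise ValueError("Ct values must be >= 0")
    fraction = amplification_base ** (-(ct_carrier - ct_library))
    if fraction > 1:
        warnings.warn("carrier Ct below library Ct: fraction exceeds 1",
                      stacklevel=2)
    return float(fraction)
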