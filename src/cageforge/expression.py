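"""Cross-sample expression profiling over consensus promoter regions.

Consensus clusters (promoter regions shared across samples) carry one
expression value per sample.  Profiles are log-transformed, optionally
row-standardized, and grouped on a small self-organizing map (SOM) grid —
the field's standard device for partitioning promoters into expression
classes (ubiquitous, sample-specific, ...).  Shifts of the dominant CTSS
within a shared region between two conditions are reported as TSS-switching
events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import rng_from_seed
from .clustering import LOCATION_CATEGORIES


@dataclass
class ExpressionMatrix:
    values: np.ndarray          # rows = consensus clusters, cols = samples
    samples: List[str]
    row_index: np.ndarray       # indices into the consensus table
    log_transformed: bool = True
    standardized: bool = False


def build_matrix(consensus: pd.DataFrame, samples: Sequence[str],
                 min_tpm: float = 1.0,
                 standardize: bool = True) -> ExpressionMatrix:
    """log10(tpm+1) expression matrix over filtered consensus clusters.

    Rows where no sample reaches *min_tpm* are dropped.  With
    *standardize*, rows are z-scored (constant rows left at 0) — the usual
    preprocessing before SOM training so that profile shape, not absolute
    level, drives the classes.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names")
    tpm = consensus[[f"tpm_{s}" for s in samples]].to_numpy(dtype=float)
    keep = (tpm >= min_tpm).any(axis=1)
    vals = np.log10(tpm[keep] + 1.0)
    if standardize:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        vals = (vals - mu) / sd
    return ExpressionMatrix(values=vals, samples=samples,
                            row_index=np.flatnonzero(keep),
                            standardized=standardize)


def som_cluster(matrix: ExpressionMatrix, grid: Tuple[int, int] = (4, 2),
                epochs: int = 50, seed: Optional[int] = 0) -> dict:
    """Batch self-organizing map over expression profiles.

    Nodes live on an ``nx x ny`` grid; each row is assigned the label
    ``"x_y"`` of its best-matching node.  Training is the standard batch
    scheme: nodes start at seeded random data rows, then each epoch every
    row is assigned to its nearest node and nodes move to the
    Gaussian-neighborhood-weighted mean of the data, with the neighborhood
    radius shrinking from half the grid diagonal to ~0.5.  Deterministic
    for a fixed seed.
    """
    nx, ny = grid
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    data = matrix.values
    n, d = data.shape
    n_nodes = nx * ny
    if n_nodes > n:
        raise ValueError(f"more grid nodes ({n_nodes}) than rows ({n})")
    rng = rng_from_seed(seed)
    coords = np.array([(x, y) for x in range(nx) for y in range(ny)], dtype=float)
    init = rng.choice(n, size=n_nodes, replace=False)
    weights = data[init] + rng.normal(scale=1e-4, size=(n_nodes, d))
    sigma0 = max(np.hypot(nx - 1, ny - 1) / 2.0, 0.5)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for epoch in range(epochs):
        sigma = sigma0 * (0.5 / sigma0) ** (epoch / max(epochs - 1, 1)) \
            if sigma0 > 0.5 else 0.5
        d2 = ((data[:, None, :] - weights[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        h = np.exp(-grid_d2 / (2 * sigma ** 2))  # node x node neighborhood
        influence = h[bmu]                        # row x node
        denom = influence.sum(axis=0)[:, None]
        nonzero = denom[:, 0] > 0
        new_w = weights.copy()
        new_w[nonzero] = (influence.T @ data)[nonzero] / denom[nonzero]
        weights = new_w
    d2 = ((data[:, None, :] - weights[None, :, :]) ** 2).sum(-1)
    bmu = d2.argmin(axis=1)
    labels = np.array([f"{int(coords[b, 0])}_{int(coords[b, 1])}" for b in bmu])
    class_means = {}
    for node in range(n_nodes):
        members = bmu == node
        key = f"{int(coords[node, 0])}_{int(coords[node, 1])}"
        class_means[key] = data[members].mean(axis=0) if members.any() else \
            weights[node]
    return {"labels": labels, "class_means": class_means, "weights": weights,
            "grid": grid}


def class_location_breakdown(labels: Sequence[str],
                             locations: Sequence[Optional[str]]) -> pd.DataFrame:
    """Per-SOM-class proportions of genomic-location categories.

    *labels* and *locations* are parallel over clusters; entries with a
    missing location are excluded (their count is recorded in the
    ``n_excluded`` attribute of the result).
    """
    if len(labels) != len(locations):
        raise ValueError("labels and locations must be parallel")
    rows: Dict[str, Dict[str, int]] = {}
    n_excluded = 0
    for lab, loc in zip(labels, locations):
        if loc is None or (isinstance(loc, float) and np.isnan(loc)):
            n_excluded += 1
            continue
        rows.setdefault(lab, {c: 0 for c in LOCATION_CATEGORIES})
        rows[lab][loc] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    out = out.div(out.sum(axis=1), axis=0)
    out.attrs["n_excluded"] = n_excluded
    return out.sort_index()


@dataclass
class SwitchEvent:
    chrom: str
    strand: str
    start: int
    end: int
    dominant_a: int
    dominant_b: int
    distance: int
    tpm_a: float
    tpm_b: float


def detect_switching(consensus: pd.DataFrame, sample_a: str, sample_b: str,
                     min_tpm: float = 5.0,
                     min_distance: int = 10) -> Tuple[List[SwitchEvent], float]:
    """TSS-switching events between two conditions.

    An event is a consensus region where both samples are expressed
    (tpm >= *min_tpm* each) and their dominant CTSSs lie >= *min_distance*
    bp apart.  Returns the events and the median switch distance (NaN when
    there are none).
    """
    for s in (sample_a, sample_b):
        if f"tpm_{s}" not in consensus.columns:
            raise ValueError(f"sample {s!r} absent from consensus table")
    events = []
    for row in consensus.itertuples(index=False):
        ta = getattr(row, f"tpm_{sample_a}")
        tb = getattr(row, f"tpm_{sample_b}")
        da = getattr(row, f"dominant_{sample_a}")
        db = getattr(row, f"dominant_{sample_b}")
        if ta < min_tpm or tb < min_tpm or pd.isna(da) or pd.isna(db):
            continue
        dist = int(abs(int(da) - int(db)))
        if dist >= min_distance:
            events.append(SwitchEvent(chrom=row.chrom, strand=row.strand,
                                      start=row.start, end=row.end,
                                      dominant_a=int(da), dominant_b=int(db),
                                      distance=dist, tpm_a=float(ta),
                                      tpm_b=float(tb)))
    median = float(np.median([e.distance for e in events])) if events else float("nan")
    return events, median
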