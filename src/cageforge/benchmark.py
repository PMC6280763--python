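"""Benchmarking a CAGE library against a reference.

A low-input library is judged by how faithfully it reproduces the CTSS and
tag-cluster landscape of a deep reference library made from abundant
material.  Agreement is quantified by (i) Pearson correlation of raw,
non-log TPM over the union of CTSS positions, (ii) ROC curves that treat
reference CTSSs / clusters as truth and rank query entities by expression,
(iii) distances between paired dominant CTSSs, (iv) per-CTSS expression
ratio heatmaps centered on the reference dominant CTSS with rows grouped by
expression quartile, and (v) a permutation test for heatmap similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import rng_from_seed
from .clustering import TagCluster

KEY = ["chrom", "pos", "strand"]


def _union_tpm(a: pd.DataFrame, b: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    merged = a[KEY + ["tpm"]].merge(b[KEY + ["tpm"]], on=KEY, how="outer",
                                    suffixes=("_a", "_b")).fillna(0.0)
    return merged["tpm_a"].to_numpy(), merged["tpm_b"].to_numpy()


def correlate_ctss(a: pd.DataFrame, b: pd.DataFrame,
                   method: str = "pearson") -> float:
    """Correlation of raw (non-log) TPM over the CTSS union of two libraries.

    Positions absent from one library enter as 0 so that missed CTSSs are
    penalized.  Raises on zero-variance input.
    """
    va, vb = _union_tpm(a, b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero-variance expression vector; correlation undefined")
    if method == "pearson":
        return float(np.corrcoef(va, vb)[0, 1])
    if method == "spearman":
        from scipy import stats
        return float(stats.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown method {method!r}")


def roc_vs_reference(query, reference, level: str = "ctss",
                     truth_min_tpm: float = 1.0):
    """ROC of query entities (ranked by descending TPM) against reference truth.

    ``level='ctss'``: truth = reference CTSS keys with tpm >= *truth_min_tpm*;
    a query CTSS is a hit when its key is in the truth set.
    ``level='cluster'``: truth = reference cluster regions; a query cluster is
    a hit when it overlaps a truth region on the same strand.

    Returns ``(fpr, tpr, auc)`` — a rank-threshold step curve with trapezoid
    AUC.
    """
    if level == "ctss":
        truth_keys = set(map(tuple, reference.loc[
            reference["tpm"] >= truth_min_tpm, KEY].itertuples(index=False)))
        if not truth_keys:
            raise ValueError("empty truth set")
        q = query.sort_values("tpm", ascending=False, kind="mergesort")
        hits = np.fromiter((tuple(k) in truth_keys
                            for k in q[KEY].itertuples(index=False)),
                           dtype=bool, count=len(q))
        n_truth = len(truth_keys)
    elif level == "cluster":
        ref_clusters = list(reference)
        if not ref_clusters:
            raise ValueError("empty truth set")
        by_key = {}
        for tc in ref_clusters:
            by_key.setdefault((tc.chrom, tc.strand), []).append((tc.start, tc.end))
        q_sorted = sorted(query, key=lambda tc: -tc.total_tpm)
        hits = np.array([any(s <= tc.end and tc.start <= e
                             for s, e in by_key.get((tc.chrom, tc.strand), []))
                         for tc in q_sorted], dtype=bool)
        n_truth = len(ref_clusters)
    else:
        raise ValueError(f"unknown level {level!r}")

    n_neg = int((~hits).sum())
    tp = np.concatenate([[0], np.cumsum(hits)])
    fp = np.concatenate([[0], np.cumsum(~hits)])
    tpr = tp / n_truth
    fpr = fp / n_neg if n_neg > 0 else np.zeros_like(fp, dtype=float)
    if n_neg == 0:
        # every candidate is a true entity: the curve rises along fpr = 0
        return fpr, tpr, 1.0
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def pair_clusters(query: Sequence[TagCluster],
                  reference: Sequence[TagCluster]) -> List[Tuple[TagCluster, TagCluster]]:
    """Pair query/reference clusters by reciprocal same-strand overlap.

    Each cluster's candidate partner is the overlapping (>= 1 bp) cluster on
    the other side sharing the most bases; a pair is kept only when the
    choice is mutual.  This keeps one pair per promoter even when a
    fragmented low-complexity query throws several slivers onto one
    reference cluster.
    """
    by_key = {}
    for tc in reference:
        by_key.setdefault((tc.chrom, tc.strand), []).append(tc)

    def overlap(a, b):
        return min(a.end, b.end) - max(a.start, b.start) + 1

    best_for_query = {}
    best_for_ref = {}
    for qi, qc in enumerate(query):
        cands = [rc for rc in by_key.get((qc.chrom, qc.strand), [])
                 if overlap(qc, rc) > 0]
        if not cands:
            continue
        rc = max(cands, key=lambda rc: overlap(qc, rc))
        best_for_query[qi] = rc
        key = id(rc)
        prev = best_for_ref.get(key)
        if prev is None or overlap(qc, rc) > overlap(query[prev], rc):
            best_for_ref[key] = qi
    return [(query[qi], rc) for qi, rc in best_for_query.items()
            if best_for_ref.get(id(rc)) == qi]


def dominant_distance_stats(query: Sequence[TagCluster],
                            reference: Sequence[TagCluster]) -> dict:
    """Distances between dominant CTSSs of overlap-paired clusters.

    Reports the distance distribution plus the fractions of pairs with
    identical dominant CTSS and with |distance| <= 10 bp.
    """
    pairs = pair_clusters(query, reference)
    dist = np.array([abs(qc.dominant_pos - rc.dominant_pos) for qc, rc in pairs])
    n = len(dist)
    return {
        "distances": dist,
        "n_pairs": n,
        "dominant_same_fraction": float((dist == 0).mean()) if n else float("nan"),
        "dominant_within_10bp_fraction": float((dist <= 10).mean()) if n else float("nan"),
    }


@dataclass
class RatioHeatmap:
    """Per-CTSS query/reference comparison around reference dominant CTSSs."""
    offsets: np.ndarray          # column grid, 5'->3' positive
    values_common: np.ndarray    # log2(query/reference) where both detect; NaN else
    values_missing: np.ndarray   # reference tpm where query missed; NaN else
    quartile: np.ndarray         # per-row expression quartile (1..4, 4 = highest)
    row_order: np.ndarray        # indices into the input reference cluster list


def ratio_heatmap(query: pd.DataFrame, reference: pd.DataFrame,
                  reference_clusters: Sequence[TagCluster],
                  window: int = 100) -> RatioHeatmap:
    """Expression-ratio heatmap centered on reference dominant CTSSs.

    One row per reference tag cluster; columns are strand-oriented offsets
    -window..+window from the cluster's dominant CTSS.  Cells where both
    libraries detect the CTSS hold log2(tpm_query / tpm_reference)
    (``values_common``); cells detected only in the reference hold the
    reference tpm (``values_missing``).  Rows are ordered within four
    reference-expression quartile blocks (highest quartile first).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    q_map = {tuple(k): v for *k, v in
             query[KEY + ["tpm"]].itertuples(index=False)}
    r_map = {tuple(k): v for *k, v in
             reference[KEY + ["tpm"]].itertuples(index=False)}
    n = len(reference_clusters)
    offsets = np.arange(-window, window + 1)
    common = np.full((n, len(offsets)), np.nan)
    missing = np.full((n, len(offsets)), np.nan)
    totals = np.array([tc.total_tpm for tc in reference_clusters])
    for i, tc in enumerate(reference_clusters):
        sign = 1 if tc.strand == "+" else -1
        for j, off in enumerate(offsets):
            key = (tc.chrom, tc.dominant_pos + sign * off, tc.strand)
            r = r_map.get(key)
            if r is None:
                continue
            q = q_map.get(key)
            if q is None or q == 0:
                missing[i, j] = r
            else:
                common[i, j] = np.log2(q / r)
    quart = np.ones(n, dtype=int)
    if n:
        edges = np.quantile(totals, [0.25, 0.5, 0.75])
        quart = 1 + np.searchsorted(edges, totals, side="right")
    order = np.lexsort((-totals, -quart))  # quartile 4 block first
    return RatioHeatmap(offsets=offsets, values_common=common[order],
                        values_missing=missing[order], quartile=quart[order],
                        row_order=order)


def permutation_similarity(mat_a: np.ndarray, mat_b: np.ndarray,
                           n_perm: int = 1000,
                           seed: Optional[int] = 0) -> Tuple[float, float]:
    """Permutation test for similarity of two positional heatmaps.

    The statistic is the Pearson correlation of the column-mean profiles
    (NaN-aware).  The null is built by independently permuting the entries
    within each row of ``mat_b``, destroying the positional alignment of its
    columns while preserving per-row value distributions.  Returns
    ``(statistic, p)`` with ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("matrices must share the column grid")

    def stat(bb):
        pa = np.nanmean(a, axis=0)
        pb = np.nanmean(bb, axis=0)
        ok = np.isfinite(pa) & np.isfinite(pb)
        return float(np.corrcoef(pa[ok], pb[ok])[0, 1])

    observed = stat(b)
    rng = rng_from_seed(seed)
    exceed = 0
    shuffled = b.copy()
    for _ in range(n_perm):
        for row in shuffled:
            rng.shuffle(row)
        if stat(shuffled) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return observed, p


def benchmark_summary(query: pd.DataFrame, reference: pd.DataFrame,
                      query_clusters: Sequence[TagCluster],
                      reference_clusters: Sequence[TagCluster],
                      truth_min_tpm: float = 1.0) -> dict:
    """One-stop agreement summary of a query library against a reference."""
    qk = set(map(tuple, query[KEY].itertuples(index=False)))
    rk = set(map(tuple, reference[KEY].itertuples(index=False)))
    dom = dominant_distance_stats(query_clusters, reference_clusters)
    _, _, auc_ctss = roc_vs_reference(query, reference, level="ctss",
                                      truth_min_tpm=truth_min_tpm)
    _, _, auc_cluster = roc_vs_reference(query_clusters, reference_clusters,
                                         level="cluster")
    ref_hit = [rc for rc in reference_clusters
               if any(qc.chrom == rc.chrom and qc.strand == rc.strand
                      and qc.start <= rc.end and rc.start <= qc.end
                      for qc in query_clusters)]
    return {
        "pearson_raw": correlate_ctss(query, reference),
        "shared_ctss_fraction": len(qk & rk) / len(rk) if rk else float("nan"),
        "shared_cluster_fraction": (len(ref_hit) / len(reference_clusters)
                                    if reference_clusters else float("nan")),
        "dominant_same_fraction": dom["dominant_same_fraction"],
        "dominant_within_10bp_fraction": dom["dominant_within_10bp_fraction"],
        "auc_ctss": auc_ctss,
        "auc_cluster": auc_cluster,
    }
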