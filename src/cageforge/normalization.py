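"""Power-law normalization of CTSS tag counts.

CAGE tag counts follow an approximate power law: the reverse-cumulative
distribution N(>=x) — the number of CTSSs with at least x tags — is close to
linear on log-log axes.  Libraries sequenced to different depths are made
comparable by fitting each library's slope alpha and mapping its counts onto
a shared referent power law (slope ``alpha_ref``, total ``T = 10^6``
normalized tags), yielding normalized tags per million (TPM).

The mapping ``tpm = scale * count**(alpha/alpha_ref)`` rescales the count
axis so the library's fitted slope becomes the referent slope, and the
common scale factor pins the normalized total at T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA_REF = 1.25
DEFAULT_FIT_RANGE = (10, 1000)
DEFAULT_TOTAL = 10**6


@dataclass
class PowerLawFit:
    """Fitted slope of a library's reverse-cumulative count distribution."""
    alpha: float
    fit_range: Tuple[float, float]
    alpha_ref: float = DEFAULT_ALPHA_REF
    T: float = DEFAULT_TOTAL
    scale: Optional[float] = None
    n_points: int = 0

    def __post_init__(self):
        lo, hi = self.fit_range
        if not lo < hi:
            raise ValueError("fit_range must satisfy x_min < x_max")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def reverse_cumulative(counts: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Return (x, N(>=x)) over the distinct count values of the library."""
    counts = np.asarray(counts)
    x = np.unique(counts)
    # counts sorted ascending: N(>=x) = total - #(< x)
    n_ge = len(counts) - np.searchsorted(np.sort(counts), x, side="left")
    return x, n_ge


def fit_power_law(table: pd.DataFrame,
                  fit_range: Tuple[float, float] = DEFAULT_FIT_RANGE,
                  alpha_ref: float = DEFAULT_ALPHA_REF,
                  T: float = DEFAULT_TOTAL) -> PowerLawFit:
    """OLS fit of -slope of log10 N(>=x) vs log10 x over distinct counts.

    Only distinct count values inside *fit_range* enter the regression (one
    point per value, so the abundant singleton counts do not dominate).
    Raises ``ValueError`` on degenerate input (< 2 distinct values in range);
    callers may fall back to :func:`normalize_simple_tpm`.
    """
    lo, hi = fit_range
    x, n_ge = reverse_cumulative(table["count"].to_numpy())
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"power-law fit needs >= 2 distinct count values in [{lo}, {hi}]; "
            f"got {int(mask.sum())}")
    res = stats.linregress(np.log10(x[mask]), np.log10(n_ge[mask]))
    return PowerLawFit(alpha=-res.slope, fit_range=(lo, hi),
                       alpha_ref=alpha_ref, T=T, n_points=int(mask.sum()))


def normalize_power_law(table: pd.DataFrame, fit: PowerLawFit,
                        alpha_ref: Optional[float] = None,
                        T: Optional[float] = None) -> pd.DataFrame:
    """Map raw counts onto the referent power law; adds a ``tpm`` column.

    ``tpm_i = scale * count_i**(alpha/alpha_ref)`` with scale chosen so the
    normalized library totals exactly T tags.  Rank order of counts is
    preserved (the exponent is positive).
    """
    alpha_ref = fit.alpha_ref if alpha_ref is None else alpha_ref
    T = fit.T if T is None else T
    counts = table["count"].to_numpy()
    if len(counts) and counts.min() <= 0:
        raise ValueError("non-positive counts cannot be normalized")
    out = table.copy()
    powered = counts.astype(float) ** (fit.alpha / alpha_ref)
    scale = T / powered.sum() if powered.sum() > 0 else 0.0
    fit.scale = scale
    out["tpm"] = scale * powered
    return out


def normalize_simple_tpm(table: pd.DataFrame, T: float = DEFAULT_TOTAL) -> pd.DataFrame:
    """Depth-only fallback: ``tpm_i = count_i * T / sum(count)``."""
    counts = table["count"].to_numpy()
    if len(counts) and counts.min() <= 0:
        raise ValueError("non-positive counts cannot be normalized")
    out = table.copy()
    total = counts.sum()
    out["tpm"] = counts * (T / total) if total > 0 else 0.0
    return out


def normalize(table: pd.DataFrame, method: str = "powerlaw",
              alpha_ref: float = DEFAULT_ALPHA_REF,
              fit_range: Tuple[float, float] = DEFAULT_FIT_RANGE,
              T: float = DEFAULT_TOTAL) -> pd.DataFrame:
    """Normalize a library, falling back to simple TPM if the fit degenerates."""
    if method == "tpm":
        return normalize_simple_tpm(table, T=T)
    if method != "powerlaw":
        raise ValueError(f"unknown normalization method {method!r}")
    try:
        fit = fit_power_law(table, fit_range=fit_range, alpha_ref=alpha_ref, T=T)
    except ValueError:
        return normalize_simple_tpm(table, T=T)
    return normalize_power_law(table, fit)
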