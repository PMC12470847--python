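"""Time-series conditioning, split-half noise ceiling, and vertex QC.

Each run is linearly detrended and z-scored, runs of a condition are
averaged, and the reliability of that average is the Spearman-Brown-corrected
Pearson correlation between the odd-run and even-run means.  That reliability
is the noise ceiling: the maximum R² a model could achieve on the averaged
series, and the denominator of the normalized R² (nR²).  Four exclusion rules
remove artifactual fits: non-positive sigma, a fit parked exactly at the
origin, amplitude outside [0.01, 3], and nR² below 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NoiseCeiling",
    "detrend_zscore",
    "average_runs",
    "split_half_reliability",
    "spearman_brown",
    "noise_ceiling",
    "normalized_r2",
    "filter_vertices",
]


@dataclass(frozen=True)
class NoiseCeiling:
    split_half_r: float
    ceiling: float


def detrend_zscore(series: np.ndarray) -> np.ndarray:
    """Remove a linear trend (OLS on the time index), then z-score."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.shape[0] < 3:
        raise ValueError("series must be 1-D with length >= 3")
    t = np.arange(y.shape[0], dtype=float)
    t -= t.mean()
    slope = (t @ (y - y.mean())) / (t @ t)
    resid = y - y.mean() - slope * t
    sd = resid.std()
    if sd < 1e-12:
        raise ValueError("series is constant after detrending")
    return resid / sd


def average_runs(runs: np.ndarray) -> np.ndarray:
    """Pointwise mean of (already conditioned) runs, shape (R, T) -> (T,)."""
    runs = np.atleast_2d(np.asarray(runs, dtype=float))
    if runs.shape[0] < 1:
        raise ValueError("need at least one run")
    return runs.mean(axis=0)


def split_half_reliability(runs: np.ndarray) -> float:
    """Pearson r between the mean odd-indexed and mean even-indexed runs."""
    runs = np.atleast_2d(np.asarray(runs, dtype=float))
    if runs.shape[0] < 2:
        raise ValueError("need at least two runs to split")
    a = runs[0::2].mean(axis=0)
    b = runs[1::2].mean(axis=0)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-12:
        raise ValueError("constant half-series")
    return float(a @ b / denom)


def spearman_brown(r: float, k: float = 2.0) -> float:
    """Prophecy formula k·r/(1+(k−1)·r), clamped to 0 for r ≤ 0.

    With k=2 it predicts the reliability of the full run set from the
    correlation of its two halves (each half already being an average).
    """
    if r > 1:
        raise ValueError("correlation cannot exceed 1")
    if r <= 0:
        return 0.0
    return k * r / (1.0 + (k - 1.0) * r)


def noise_ceiling(runs: np.ndarray, k: float = 2.0) -> NoiseCeiling:
    """Split-half r and its Spearman-Brown-corrected ceiling for one vertex."""
    r = split_half_reliability(runs)
    return NoiseCeiling(split_half_r=r, ceiling=spearman_brown(r, k))


def normalized_r2(r2: float, ceiling: float, square_ceiling: bool = False) -> float:
    """R² divided by the noise ceiling; 0 when the ceiling is 0.

    ``square_ceiling`` divides by ceiling² instead (the alternative reading
    where the reliability correlation is squared before use).
    """
    if not (0 <= r2 <= 1):
        raise ValueError("r2 must be in [0, 1]")
    c = ceiling * ceiling if square_ceiling else ceiling
    if c <= 0:
        return 0.0
    return r2 / c


#: QC rules in evaluation order; `reason` records the first violated rule.
_RULES = ("sigma", "origin", "beta", "nr2")


def filter_vertices(fits: pd.DataFrame) -> pd.DataFrame:
    """Apply the four exclusion rules to a fit table.

    keep iff sigma > 0, not (x0 == 0 and y0 == 0), 0.01 <= beta <= 3, and
    nr2 >= 0.2 (boundary values kept).  Returns the table with ``keep`` and
    ``reason`` columns added; the input order is preserved and re-running on
    the output is a no-op on those columns.
    """
    required = {"sigma_deg", "x0_deg", "y0_deg", "beta", "nr2"}
    missing = required - set(fits.columns)
    if missing:
        raise KeyError(f"fit table missing columns: {sorted(missing)}")
    out = fits.copy()
    sigma_bad = out["sigma_deg"] <= 0
    origin_bad = (out["x0_deg"] == 0) & (out["y0_deg"] == 0)
    beta_bad = (out["beta"] < 0.01) | (out["beta"] > 3)
    nr2_bad = out["nr2"] < 0.2
    out["keep"] = ~(sigma_bad | origin_bad | beta_bad | nr2_bad)
    reason = np.full(len(out), "", dtype=object)
    for name, bad in zip(_RULES, (sigma_bad, origin_bad, beta_bad, nr2_bad)):
        unassigned = (reason == "") & bad.to_numpy()
        reason[unassigned] = name
    out["reason"] = reason
    return out
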