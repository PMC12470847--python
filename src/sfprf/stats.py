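"""Group statistics for adapted pRF size maps.

Per participant, pRF sizes under the two adapter conditions are compared with
Mood's median test (nonparametric — the size distribution is zero-bounded and
skewed); across participants, medians enter an ROI × adapted-SF
repeated-measures ANOVA with Greenhouse-Geisser correction.  Spatial
structure is summarized by per-vertex high-minus-low size differences binned
into 100 sliding 1°-wide eccentricity bins (per-bin median, then
between-participant mean ± SEM), plus a symmetric proportional-change
measure that makes regions with different absolute sizes comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MedianTestResult",
    "BinnedProfile",
    "RMAnovaResult",
    "moods_median_test",
    "size_difference",
    "proportional_difference",
    "sliding_bins",
    "group_profile",
    "rm_anova_roi_sf",
    "group_summary",
]


@dataclass(frozen=True)
class MedianTestResult:
    pooled_median: float
    table: np.ndarray  # 2x2: rows above/not-above pooled median, cols groups
    chi2: float
    df: int
    p_value: float
    degenerate: bool = False


def moods_median_test(a, b, ties: str = "below") -> MedianTestResult:
    """Mood's median test: 2×2 counts vs the pooled median, Pearson χ², df=1.

    No continuity correction; values tied with the pooled median count as
    "not above" by default (``ties='below'``; 'above' switches the
    convention).  A degenerate table (all values identical) returns p = 1
    with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    med = float(np.median(pooled))
    try:
        res = sps.median_test(a, b, ties=ties, correction=False)
    except ValueError:
        table = np.array(
            [[0, 0], [a.size, b.size]]
            if ties == "below"
            else [[a.size, b.size], [0, 0]]
        )
        return MedianTestResult(med, table, 0.0, 1, 1.0, degenerate=True)
    return MedianTestResult(
        pooled_median=float(res.median),
        table=np.asarray(res.table),
        chi2=float(res.statistic),
        df=1,
        p_value=float(res.pvalue),
    )


def size_difference(
    fits_high: pd.DataFrame,
    fits_low: pd.DataFrame,
    matching: str = "intersection",
) -> pd.DataFrame:
    """Per-vertex σ_high − σ_low with the between-condition mean eccentricity.

    Requires columns vertex_id, sigma_deg, ecc_deg.  ``matching`` is
    'intersection' here by construction: the difference is only defined on
    vertices present (i.e. QC-passed) in both conditions.
    """
    if matching not in ("intersection", "per-condition"):
        raise ValueError("matching must be 'intersection' or 'per-condition'")
    merged = fits_high.merge(
        fits_low, on="vertex_id", suffixes=("_high", "_low"), how="inner"
    )
    if merged.empty:
        raise ValueError("no shared vertex ids between conditions")
    return pd.DataFrame(
        {
            "vertex_id": merged["vertex_id"],
            "diff_deg": merged["sigma_deg_high"] - merged["sigma_deg_low"],
            "ecc_deg": (merged["ecc_deg_high"] + merged["ecc_deg_low"]) / 2,
        }
    )


def proportional_difference(sigma_high, sigma_low):
    """Symmetric percent-style change: (σH − σL) / ((σH + σL)/2).

    Antisymmetric in its arguments and bounded in (−2, 2); makes size changes
    comparable across regions whose absolute pRF sizes differ."""
    sh = np.asarray(sigma_high, dtype=float)
    sl = np.asarray(sigma_low, dtype=float)
    if np.any(sh <= 0) or np.any(sl <= 0):
        raise ValueError("pRF sizes must be positive")
    out = (sh - sl) / ((sh + sl) / 2.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class BinnedProfile:
    """Sliding-window eccentricity profile of per-bin median differences."""

    centers: np.ndarray
    medians: np.ndarray  # NaN where the bin has fewer than min_count points
    counts: np.ndarray


def sliding_bins(
    ecc: np.ndarray,
    values: np.ndarray,
    n_bins: int = 100,
    width: float = 1.0,
    ecc_range: tuple[float, float] = (0.0, 8.0),
    min_count: int = 10,
) -> BinnedProfile:
    """Per-bin medians over ``n_bins`` sliding windows of ``width`` degrees.

    Bin centres are evenly spaced over [lo + width/2, hi − width/2]; bin b
    collects points with ecc in [centre − width/2, centre + width/2).  Bins
    with fewer than ``min_count`` points are NaN.
    """
    ecc = np.asarray(ecc, dtype=float)
    values = np.asarray(values, dtype=float)
    if ecc.shape != values.shape or ecc.size == 0:
        raise ValueError("ecc and values must be nonempty and equal length")
    lo, hi = ecc_range
    if hi - width < lo:
        raise ValueError("range narrower than the bin width")
    centers = np.linspace(lo + width / 2, hi - width / 2, n_bins)
    medians = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for i, c in enumerate(centers):
        sel = (ecc >= c - width / 2) & (ecc < c + width / 2)
        counts[i] = int(sel.sum())
        if counts[i] >= min_count:
            medians[i] = float(np.median(values[sel]))
    return BinnedProfile(centers=centers, medians=medians, counts=counts)


def group_profile(profiles: list[BinnedProfile]) -> pd.DataFrame:
    """Average per-participant bin medians: mean and between-participant SEM.

    A bin is valid where at least two participants contribute a value.
    """
    if not profiles:
        raise ValueError("no profiles")
    centers = profiles[0].centers
    stack = np.vstack([p.medians for p in profiles])
    n = np.sum(~np.isnan(stack), axis=0)
    nz = np.maximum(n, 1)
    avg = np.nansum(np.nan_to_num(stack), axis=0) / nz
    sq = np.nansum(np.nan_to_num((stack - avg) ** 2, nan=0.0), axis=0)
    sd = np.sqrt(sq / np.maximum(n - 1, 1))
    sem = np.where(n > 1, sd / np.sqrt(nz), np.nan)
    mean = np.where(n > 1, avg, np.nan)
    return pd.DataFrame(
        {"ecc_center": centers, "mean_diff": mean, "sem": sem, "n_participants": n}
    )


@dataclass
class RMAnovaResult:
    table: pd.DataFrame  # per effect: F, df, eps, corrected p

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[self.table["effect"] == name].iloc[0]


def rm_anova_roi_sf(medians: pd.DataFrame) -> RMAnovaResult:
    """Two-way within-subject ANOVA of median pRF size on ROI × adapted SF.

    ``medians`` needs columns participant, roi, sf, sigma (one row per cell,
    complete and balanced).  Effects with more than one df receive the
    Greenhouse-Geisser epsilon; corrected df are eps-scaled.
    """
    import pingouin as pg

    required = {"participant", "roi", "sf", "sigma"}
    if not required <= set(medians.columns):
        raise KeyError(f"need columns {sorted(required)}")
    counts = medians.groupby(["participant", "roi", "sf"]).size()
    n_cells = (
        medians["participant"].nunique()
        * medians["roi"].nunique()
        * medians["sf"].nunique()
    )
    if (counts != 1).any() or len(counts) != n_cells:
        raise ValueError("table must be complete with one value per cell")
    with np.errstate(invalid="ignore"):  # degenerate 0/0 cells handled below
        res = pg.rm_anova(
            data=medians,
            dv="sigma",
            within=["roi", "sf"],
            subject="participant",
            correction=True,
            detailed=True,
        )
    p_corr = res["p_GG_corr"] if "p_GG_corr" in res else res["p_unc"]
    eps = res["eps"] if "eps" in res else 1.0
    # a noise-free null effect has 0/0 for F; report it as no effect
    null_effect = res["SS"] < 1e-12
    res.loc[null_effect, "F"] = 0.0
    res.loc[null_effect, "p_unc"] = 1.0
    p_corr = p_corr.where(~null_effect, 1.0)
    table = pd.DataFrame(
        {
            "effect": res["Source"].str.replace(" * ", ":", regex=False),
            "F": res["F"],
            "df1": res["ddof1"],
            "df2": res["ddof2"],
            "eps": eps,
            "df1_corr": res["ddof1"] * eps,
            "df2_corr": res["ddof2"] * eps,
            "p_uncorrected": res["p_unc"],
            "p_gg": p_corr,
        }
    )
    return RMAnovaResult(table=table)


def group_summary(
    fits: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per participant × ROI medians and Mood's tests (high vs low), with
    Benjamini-Hochberg FDR across the whole test family.

    ``fits`` needs columns participant, roi, condition ('high_adapted' /
    'low_adapted'), sigma_deg; pass only QC-passed rows.  Returns
    (medians table, tests table); ``significant`` marks q < alpha.
    """
    required = {"participant", "roi", "condition", "sigma_deg"}
    if not required <= set(fits.columns):
        raise KeyError(f"need columns {sorted(required)}")
    med = (
        fits.groupby(["participant", "roi", "condition"])["sigma_deg"]
        .median()
        .reset_index(name="median_sigma")
    )
    rows = []
    for (p, roi), grp in fits.groupby(["participant", "roi"]):
        hi = grp.loc[grp["condition"] == "high_adapted", "sigma_deg"].to_numpy()
        lo = grp.loc[grp["condition"] == "low_adapted", "sigma_deg"].to_numpy()
        if hi.size == 0 or lo.size == 0:
            continue
        res = moods_median_test(hi, lo)
        rows.append(
            {
                "participant": p,
                "roi": roi,
                "n_high": hi.size,
                "n_low": lo.size,
                "median_high": float(np.median(hi)),
                "median_low": float(np.median(lo)),
                "chi2": res.chi2,
                "p_value": res.p_value,
            }
        )
    tests = pd.DataFrame(rows)
    if not tests.empty:
        rej, q, _, _ = multipletests(
            tests["p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        tests["q_value"] = q
        tests["significant"] = rej
        tests["direction_high_gt_low"] = tests["median_high"] > tests["median_low"]
    return med, tests
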