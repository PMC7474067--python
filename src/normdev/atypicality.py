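"""Outlier flagging, prevalence maps, prevalence testing and global
deviation ratios derived from a w-score matrix.

A region-wise outlier is a subject whose |w| strictly exceeds the
threshold (default 2 SD); boundary cells count as non-outliers. The global
w-score ratio gW for a subject is the count of outlier regions divided by
the count of non-outlier regions, with signed variants gW+ / gW- whose
numerators use only positive / negative deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

OUTLIER_THRESHOLD = 2.0
GLOBAL_RATIO_CUTOFF = 0.5


def flag_outliers(w: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD) -> pd.DataFrame:
    """Boolean subject x region matrix, True where |w| > threshold (strict).

    Missing w cells are False; the missing count is logged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n_missing = int(w.isna().sum().sum())
    if n_missing:
        logger.info("flag_outliers: %d missing w cells treated as unflagged", n_missing)
    return w.abs() > threshold  # NaN comparisons are False


@dataclass
class PrevalenceSummary:
    per_region: pd.Series       # proportion flagged per region
    counts: pd.Series           # flag counts per region
    median: float
    distribution: np.ndarray    # prevalence values across regions


def region_prevalence(flags: pd.DataFrame, group_n: int | None = None) -> PrevalenceSummary:
    """Per-region proportion of flagged subjects plus the across-region
    distribution (the prevalence-map analogue)."""
    if group_n is None:
        group_n = len(flags)
    if group_n <= 0:
        raise ValueError("group_n must be > 0")
    counts = flags.sum(axis=0)
    prev = counts / group_n
    return PrevalenceSummary(per_region=prev, counts=counts,
                             median=float(prev.median()),
                             distribution=prev.to_numpy())


def prevalence_chisq(
    p_obs: float,
    p0: float,
    n: int,
    yates: bool = True,
) -> tuple[float, float]:
    """One-sample proportion chi-square against an expected proportion.

    ``X2 = n * (|p_obs - p0| - c)^2 / (p0 * (1 - p0))`` with the Yates
    continuity correction ``c = 1/(2n)`` (capped so the corrected
    difference is never negative); p from chi-square with 1 df.
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if n <= 0:
        raise ValueError("n must be > 0")
    diff = abs(p_obs - p0)
    if yates:
        diff = max(0.0, diff - 1.0 / (2 * n))
    x2 = n * diff**2 / (p0 * (1 - p0))
    p = float(stats.chi2.sf(x2, df=1)) if x2 > 0 else 1.0
    return float(x2), p


@dataclass
class GlobalRatio:
    gw: float
    gw_pos: float
    gw_neg: float
    n_outlier: int
    n_non_outlier: int
    infinite: bool = False


def global_w_ratio(
    w_row: pd.Series | np.ndarray,
    threshold: float = OUTLIER_THRESHOLD,
) -> GlobalRatio:
    """Per-subject global deviation ratio (outlier regions / non-outlier
    regions), plus signed variants.

    Missing cells are excluded from both numerator and denominator. A zero
    denominator returns inf with the ``infinite`` flag set.
    """
    v = np.asarray(w_row, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("all w values missing for this subject")
    v = v[ok]
    out = np.abs(v) > threshold
    n_out, n_in = int(out.sum()), int((~out).sum())
    n_pos = int((v > threshold).sum())
    n_neg = int((v < -threshold).sum())
    if n_in == 0:
        return GlobalRatio(np.inf, np.inf if n_pos else 0.0,
                           np.inf if n_neg else 0.0, n_out, 0, infinite=True)
    return GlobalRatio(n_out / n_in, n_pos / n_in, n_neg / n_in, n_out, n_in)


def global_w_ratios(
    w: pd.DataFrame,
    threshold: float = OUTLIER_THRESHOLD,
    global_thin_cutoff: float = GLOBAL_RATIO_CUTOFF,
) -> pd.DataFrame:
    """gW, gW+, gW- per subject; ``global_thin`` marks gW- > cutoff
    (globally thinner cortex). Subjects with no scorable region get NaN
    ratios (counted in the log) rather than raising."""
    rows = []
    n_unscorable = 0
    for sid, row in w.iterrows():
        try:
            r = global_w_ratio(row, threshold)
        except ValueError:
            n_unscorable += 1
            rows.append(dict(subject_id=sid, gw=np.nan, gw_pos=np.nan,
                             gw_neg=np.nan, n_outlier=0, n_non_outlier=0,
                             infinite=False))
            continue
        rows.append(dict(subject_id=sid, gw=r.gw, gw_pos=r.gw_pos, gw_neg=r.gw_neg,
                         n_outlier=r.n_outlier, n_non_outlier=r.n_non_outlier,
                         infinite=r.infinite))
    if n_unscorable:
        logger.info("global_w_ratios: %d subjects with no scorable region", n_unscorable)
    out = pd.DataFrame(rows).set_index("subject_id")
    out["global_thin"] = out["gw_neg"] > global_thin_cutoff
    return out


@dataclass
class OutlierAgeSummary:
    per_region: pd.Series     # median outlier age per region (NaN if none)
    pooled: np.ndarray        # distribution of per-region medians
    range: tuple[float, float]


def outlier_age_summary(flags: pd.DataFrame, cohort) -> OutlierAgeSummary:
    """Median age of flagged subjects per region and the pooled
    across-region distribution of those medians."""
    ages = cohort.ages_by_id().reindex(flags.index)
    med = {}
    for region in flags.columns:
        sel = flags[region].to_numpy(dtype=bool)
        med[region] = float(np.median(ages.to_numpy()[sel])) if sel.any() else np.nan
    per_region = pd.Series(med)
    pooled = per_region.dropna().to_numpy()
    rng = (float(pooled.min()), float(pooled.max())) if pooled.size else (np.nan, np.nan)
    return OutlierAgeSummary(per_region=per_region, pooled=pooled, range=rng)
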