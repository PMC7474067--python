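"""Mass-univariate inference: mixed-model case-control contrasts,
one-sample w-score tests, brain-behaviour correlation maps, BH-FDR and
a-priori power calculations.

Region models are linear mixed models with a random intercept per site
(statsmodels MixedLM); with a single site the model degenerates to OLS,
which with no covariates reproduces the pooled-variance two-sample t-test
exactly. Cohen's d is the group coefficient divided by the model residual
SD, with the sign convention case - control throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import CohortTable

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "motion_fd", "euler")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags.

    q-values are ``p * m / rank`` with enforced monotonicity from the
    largest p downward; flags mark ``q_value < q``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, qvals < q


# ---------------------------------------------------------------------------
# Region-wise mixed model
# ---------------------------------------------------------------------------

@dataclass
class RegionFit:
    estimate: float
    se: float
    p: float
    d: float
    n: int
    method: str  # "lme" or "ols"
    converged: bool = True


def _wald_p_and_d(est: float, se: float, resid_sd: float, df: int) -> tuple[float, float]:
    """Wald p on the residual-df t reference; degenerate (zero-variance) fits
    collapse to p = 1 for a zero estimate."""
    if se <= 0 or not np.isfinite(se):
        p = 1.0 if est == 0 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(est / se), df))
    d = est / resid_sd if resid_sd > 0 else 0.0
    return p, float(d)


def _design(cohort_df: pd.DataFrame, covariates, include_group: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort_df.index)
    X["Intercept"] = 1.0
    if include_group:
        X["group_case"] = (cohort_df["group"] == "case").astype(float)
    for cov in covariates:
        if cov == "sex":
            if cohort_df["sex"].nunique() > 1:
                X["sex_female"] = (cohort_df["sex"] == "female").astype(float)
        else:
            X[cov] = cohort_df[cov].astype(float)
    return X


def fit_region_lme(
    values: np.ndarray | pd.Series,
    cohort: CohortTable,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    include_group: bool = True,
) -> RegionFit:
    """Fit ``value ~ group + covariates + (1 | site)`` for one region.

    Subjects with a missing covariate or value are excluded from the model
    (per-model exclusion, counted in the log). With a single site the model
    falls back to OLS with a logged warning. Returns the group coefficient
    (or the intercept when ``include_group=False``), its SE, a Wald p-value
    on the residual-df t reference, and Cohen's d = coefficient / residual
    SD (sign convention case - control).
    """
    y = pd.Series(np.asarray(values, dtype=float), index=cohort.df.index)
    X = _design(cohort.df, covariates, include_group)
    keep = y.notna() & X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_region_lme: excluded %d subjects with missing data", n_dropped)
    y, X = y[keep], X[keep]
    df_cohort = cohort.df[keep.to_numpy()]
    if include_group and df_cohort["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    term = "group_case" if include_group else "Intercept"

    n_sites = df_cohort["site"].nunique()
    n, k = X.shape
    if n_sites < 2:
        if include_group and not getattr(fit_region_lme, "_warned_single_site", False):
            logger.warning("fit_region_lme: single site; falling back to OLS "
                           "(reported once per process)")
            fit_region_lme._warned_single_site = True
        import statsmodels.api as sm
        res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        j = list(X.columns).index(term)
        est, se = float(res.params[j]), float(res.bse[j])
        resid_sd = float(np.sqrt(res.scale))
        p, d = _wald_p_and_d(est, se, resid_sd, n - k)
        return RegionFit(est, se, p, d, n, "ols")

    import statsmodels.api as sm
    groups = df_cohort["site"].to_numpy()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = sm.MixedLM(y.to_numpy(), X.to_numpy(), groups=groups)
            res = md.fit(reml=True, method="lbfgs")
            converged = bool(res.converged)
        except (np.linalg.LinAlgError, ValueError):
            converged = False
            res = None
    if res is None or not np.all(np.isfinite(res.params)):
        return RegionFit(np.nan, np.nan, np.nan, np.nan, n, "lme", converged=False)
    j = list(X.columns).index(term)
    est, se = float(res.params[j]), float(res.bse[j])
    resid_sd = float(np.sqrt(res.scale))
    p, d = _wald_p_and_d(est, se, resid_sd, n - k)  # residual-df approximation
    return RegionFit(est, se, p, d, n, "lme", converged=converged)


def _stats_table(rows: list[dict], label: str, fdr_q: float) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    table["analysis"] = label
    ok = table["p"].notna()
    table["q"] = np.nan
    table["significant"] = False
    if ok.any():
        qvals, flags = bh_fdr(table.loc[ok, "p"].to_numpy(), q=fdr_q)
        table.loc[ok, "q"] = qvals
        table.loc[ok, "significant"] = flags
    return table


def case_control_map(
    morph_df: pd.DataFrame,
    cohort: CohortTable,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    fdr_q: float = 0.05,
    label: str = "case_control",
) -> pd.DataFrame:
    """Region-wise mixed-model case-control contrast with BH-FDR."""
    ids = morph_df.index.intersection(cohort.subject_ids)
    sub = cohort.subset(cohort.df["subject_id"].isin(ids))
    block = morph_df.loc[sub.df["subject_id"]]
    rows = []
    for region in morph_df.columns:
        try:
            fit = fit_region_lme(block[region].to_numpy(), sub, covariates)
            rows.append(dict(region=region, estimate=fit.estimate, se=fit.se,
                             d=fit.d, p=fit.p, n=fit.n, method=fit.method))
        except ValueError as exc:
            logger.warning("case_control_map: region %s skipped (%s)", region, exc)
            rows.append(dict(region=region, estimate=np.nan, se=np.nan, d=np.nan,
                             p=np.nan, n=0, method="failed"))
    return _stats_table(rows, label, fdr_q)


@dataclass
class OutlierRemovalResult:
    before: pd.DataFrame
    after: pd.DataFrame
    n_significant_before: int
    n_significant_after: int
    ratio: float
    n_removed_cells: int
    unstable_regions: list[str]


def remove_region_outliers_and_refit(
    morph_df: pd.DataFrame,
    w: pd.DataFrame,
    cohort: CohortTable,
    threshold: float = 2.0,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    fdr_q: float = 0.05,
    min_cases: int = 10,
) -> OutlierRemovalResult:
    """Drop case subjects with |w| > threshold region-wise and refit.

    Removal applies to the case group only and per region (a subject is
    removed only from the regions where they are an outlier). Reports the
    count of FDR-significant regions before vs after and their ratio.
    """
    before = case_control_map(morph_df, cohort, covariates, fdr_q, "case_control")
    ids = morph_df.index.intersection(cohort.subject_ids)
    sub = cohort.subset(cohort.df["subject_id"].isin(ids))
    block = morph_df.loc[sub.df["subject_id"]]
    is_case = (sub.df["group"] == "case").to_numpy()
    w_al = w.reindex(index=block.index, columns=block.columns)

    rows, unstable, removed = [], [], 0
    for region in block.columns:
        drop = is_case & (w_al[region].abs() > threshold).to_numpy()
        removed += int(drop.sum())
        keep = ~drop
        kept_cases = int((is_case & keep).sum())
        if kept_cases < min_cases:
            unstable.append(region)
            rows.append(dict(region=region, estimate=np.nan, se=np.nan, d=np.nan,
                             p=np.nan, n=int(keep.sum()), method="unstable"))
            continue
        try:
            fit = fit_region_lme(block[region].to_numpy()[keep], sub.subset(keep),
                                 covariates)
            rows.append(dict(region=region, estimate=fit.estimate, se=fit.se,
                             d=fit.d, p=fit.p, n=fit.n, method=fit.method))
        except ValueError:
            rows.append(dict(region=region, estimate=np.nan, se=np.nan, d=np.nan,
                             p=np.nan, n=int(keep.sum()), method="failed"))
    after = _stats_table(rows, "case_control_outlier_removed", fdr_q)
    n_before = int(before["significant"].sum())
    n_after = int(after["significant"].sum())
    ratio = n_before / n_after if n_after else np.inf
    logger.info("outlier removal: %d -> %d significant regions (%.2f-fold), "
                "%d case*region cells removed", n_before, n_after,
                ratio if np.isfinite(ratio) else -1, removed)
    return OutlierRemovalResult(before, after, n_before, n_after, float(ratio),
                                removed, unstable)


def wscore_one_sample(
    w: pd.DataFrame,
    cohort: CohortTable,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-region test of the case-group w-scores against zero.

    Mixed model ``w ~ 1 + (1 | site)`` on the case group (OLS intercept
    when a single site), BH-FDR across regions.
    """
    cases = cohort.filter_group("case") if (cohort.df["group"] == "control").any() \
        else cohort
    ids = w.index.intersection(cases.subject_ids)
    sub = cases.subset(cases.df["subject_id"].isin(ids))
    block = w.loc[sub.df["subject_id"]]
    rows = []
    for region in w.columns:
        vals = block[region]
        try:
            fit = fit_region_lme(vals.to_numpy(), sub, covariates=(),
                                 include_group=False)
            rows.append(dict(region=region, estimate=fit.estimate, se=fit.se,
                             d=fit.d, p=fit.p, n=fit.n, method=fit.method))
        except ValueError:
            rows.append(dict(region=region, estimate=np.nan, se=np.nan, d=np.nan,
                             p=np.nan, n=0, method="failed"))
    return _stats_table(rows, "wscore_one_sample", fdr_q)


# ---------------------------------------------------------------------------
# Brain-behaviour maps
# ---------------------------------------------------------------------------

def _spearman(x: np.ndarray, y: np.ndarray, exact_below: int = 31) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return np.nan, np.nan
    n = x.size
    if n < exact_below:  # permutation p at small n; t approximation above
        def statistic(perm_y):
            return stats.spearmanr(x, perm_y).statistic
        res = stats.permutation_test((y,), statistic, permutation_type="pairings",
                                     n_resamples=2000, alternative="two-sided",
                                     random_state=0)
        p = float(res.pvalue)
    return float(rho), float(p)


def spearman_phenotype_map(
    w: pd.DataFrame,
    phenotypes: pd.DataFrame,
    fdr_q: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman rho per region x phenotype, one joint BH-FDR family.

    Missing phenotype or w values are handled pairwise-complete per
    region x phenotype; pairs below ``min_pairs`` (or constant inputs) are
    reported missing. The FDR family is all phenotype x region tests
    jointly.
    """
    ids = w.index.intersection(phenotypes.index)
    wb = w.loc[ids]
    ph = phenotypes.loc[ids]
    rows = []
    for pheno in ph.columns:
        pv = ph[pheno].to_numpy(dtype=float)
        for region in wb.columns:
            wv = wb[region].to_numpy(dtype=float)
            ok = np.isfinite(pv) & np.isfinite(wv)
            if ok.sum() < min_pairs or np.unique(pv[ok]).size < 2 \
                    or np.unique(wv[ok]).size < 2:
                rows.append(dict(region=region, phenotype=pheno, rho=np.nan,
                                 p=np.nan, n=int(ok.sum())))
                continue
            rho, p = _spearman(wv[ok], pv[ok])
            rows.append(dict(region=region, phenotype=pheno, rho=rho, p=p,
                             n=int(ok.sum())))
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["q"] = np.nan
    table["significant"] = False
    if ok.any():
        qvals, flags = bh_fdr(table.loc[ok, "p"].to_numpy(), q=fdr_q)
        table.loc[ok, "q"] = qvals
        table.loc[ok, "significant"] = flags
    table["analysis"] = "spearman:" + table["phenotype"]
    return table


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def _nct_two_sided_power(t_crit: float, df: float, ncp: float) -> float:
    p = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(p):  # scipy nct underflows at large df*ncp; normal limit
        p = stats.norm.sf(t_crit - ncp) + stats.norm.cdf(-t_crit - ncp)
    return float(p)


def min_detectable_d(n_per_group: int, alpha: float, power: float) -> float:
    """Smallest Cohen's d detectable by a two-sided two-sample t-test.

    Solves the noncentral-t power equation (df = 2n - 2, ncp = d * sqrt(n/2))
    for d.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    df = 2 * n_per_group - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)

    def gap(d: float) -> float:
        return _nct_two_sided_power(t_crit, df, d * np.sqrt(n_per_group / 2.0)) - power

    if gap(1e-12) > 0:  # power below alpha is unreachable
        return 0.0
    hi = 1.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise ValueError("power equation unsolvable at this configuration")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=1e-10))


def min_detectable_r(n: int, alpha: float, power: float) -> float:
    """Smallest correlation detectable by the two-sided r-to-t test.

    Uses the t statistic ``r * sqrt((n-2)/(1-r^2))`` with n - 2 df and a
    noncentral-t power equation solved for r.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    df = n - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)

    def gap(r: float) -> float:
        ncp = r * np.sqrt(df) / np.sqrt(1 - r * r)
        return _nct_two_sided_power(t_crit, df, ncp) - power

    if gap(1e-12) > 0:
        return 0.0
    if gap(1 - 1e-9) < 0:
        raise ValueError("power equation unsolvable at this configuration")
    return float(optimize.brentq(gap, 1e-12, 1 - 1e-9, xtol=1e-12))


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_exclusion_maps(
    morph_df: pd.DataFrame,
    cohort: CohortTable,
    rank_covariate: str,
    top_fractions: list[float],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Effect-size map stability under top-covariate exclusion.

    Recomputes the per-region Cohen's d map after excluding the worst
    ``fraction`` of subjects by ``rank_covariate`` and reports the Pearson
    correlation with the full-sample map per fraction.
    """
    if rank_covariate not in ("motion_fd", "euler"):
        raise ValueError("rank_covariate must be 'motion_fd' or 'euler'")
    vals = cohort.df[rank_covariate].to_numpy(dtype=float)
    if not np.isfinite(vals).any():
        raise ValueError(f"{rank_covariate} entirely missing")
    full = case_control_map(morph_df, cohort, covariates)
    d_full = full.set_index("region")["d"]
    rows = []
    for frac in top_fractions:
        if frac >= 0.5:
            raise ValueError("exclusion fraction >= 0.5 is degenerate")
        if frac <= 0:
            rows.append(dict(fraction=float(frac), r=1.0, n_excluded=0))
            continue
        cutoff = np.nanquantile(vals, 1 - frac)
        keep = ~(np.isfinite(vals) & (vals > cutoff))
        reduced = case_control_map(morph_df, cohort.subset(keep), covariates)
        d_red = reduced.set_index("region")["d"]
        ok = d_full.notna() & d_red.notna()
        r = float(np.corrcoef(d_full[ok], d_red[ok])[0, 1]) if ok.sum() > 2 else np.nan
        rows.append(dict(fraction=float(frac), r=r, n_excluded=int((~keep).sum())))
    return pd.DataFrame(rows)
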