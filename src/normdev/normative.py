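"""Age-normative estimation per region and conversion to deviation scores.

The normative model for a region is a LOESS mean trajectory fit on the
control group, tabulated into one-year age bins: each retained bin stores
the median fitted mean, the SD of the observed-minus-fitted residuals and
the control count. A subject's w-score in a region is then
``(value - bin_mean) / bin_sd``, i.e. an age-normed z-score. Bins with
fewer than ``min_bin_count`` controls (or near-zero SD) are dropped and
yield missing w-scores.

The LOESS smoothing span is chosen per region by bounded scalar
minimization (Brent) of either a 5-fold cross-validated SSE (default) or
the training-sample SSE (``sse_mode="literal"``; this objective shrinks
monotonically with span and is kept only for comparability, bounded below
by the minimum span).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .io_core import CohortTable, MorphMatrix
from .inference import bh_fdr

logger = logging.getLogger(__name__)

SPAN_BOUNDS = (0.05, 1.0)
MIN_BIN_COUNT = 5
SD_FLOOR = 1e-6  # bins with sd below this are unusable (w would blow up)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def _window_starts(xs: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest contiguous window in sorted xs per query."""
    n = xs.size
    starts = np.empty(q.size, dtype=np.intp)
    pos = np.searchsorted(xs, q)
    for j in range(q.size):
        lo = max(0, pos[j] - k)
        hi = min(n - k, pos[j])
        if hi < lo:
            starts[j] = max(0, min(pos[j], n - k))
            continue
        cand = np.arange(lo, hi + 1)
        maxd = np.maximum(q[j] - xs[cand], xs[cand + k - 1] - q[j])
        starts[j] = cand[np.argmin(maxd)]
    return starts


def fit_loess(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    degree: int = 1,
    x_query: np.ndarray | None = None,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    At each query point the ``ceil(span * n)`` nearest neighbours (at least
    ``degree + 2``) form the window; points are weighted by
    ``(1 - (d/h)^3)^3`` with ``h`` the window radius, and a degree-1 or -2
    weighted least-squares polynomial is evaluated at the query point.

    Raises
    ------
    ValueError
        On invalid span/degree or a degenerate window (all x identical).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points")

    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    q = xs if x_query is None else np.asarray(x_query, dtype=float)
    k = min(n, max(degree + 2, int(np.ceil(span * n))))

    starts = _window_starts(xs, q, k)
    idx = starts[:, None] + np.arange(k)[None, :]
    xw, yw = xs[idx], ys[idx]
    d = np.abs(xw - q[:, None])
    h = d.max(axis=1)
    if np.any(h <= 0):
        raise ValueError("degenerate LOESS window: all x identical")
    u = d / h[:, None]
    w = np.clip(1.0 - u**3, 0.0, None) ** 3
    dead = w.sum(axis=1) <= 0
    if dead.any():  # pathological ties at the window boundary
        w[dead] = 1.0

    xc = xw - q[:, None]
    if degree == 1:
        s0 = w.sum(axis=1)
        s1 = (w * xc).sum(axis=1)
        s2 = (w * xc**2).sum(axis=1)
        t0 = (w * yw).sum(axis=1)
        t1 = (w * xc * yw).sum(axis=1)
        denom = s0 * s2 - s1**2
        if np.any(denom <= np.finfo(float).tiny * 100):
            raise ValueError("degenerate LOESS window: all x identical")
        fitted = (s2 * t0 - s1 * t1) / denom
    else:
        pw = np.stack([np.ones_like(xc), xc, xc**2], axis=2)  # (nq, k, 3)
        A = np.einsum("qki,qkj,qk->qij", pw, pw, w)
        b = np.einsum("qki,qk,qk->qi", pw, w, yw)
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate LOESS window") from exc
        fitted = beta[:, 0]
    if x_query is None:
        # undo the sort so fitted values align with the input order
        out = np.empty_like(fitted)
        out[order] = fitted
        return out
    return fitted


def _cv_sse(x, y, span, degree, n_folds, seed) -> float:
    rng = np.random.default_rng(seed)
    n = x.size
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    sse = 0.0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if mask.sum() < degree + 2:
            continue
        pred = fit_loess(x[mask], y[mask], span, degree, x_query=x[fold])
        sse += float(np.sum((y[fold] - pred) ** 2))
    return sse


def _training_sse(x, y, span, degree) -> float:
    fitted = fit_loess(x, y, span, degree)
    return float(np.sum((y - fitted) ** 2))


def optimize_span(
    x: np.ndarray,
    y: np.ndarray,
    bounds: tuple[float, float] = SPAN_BOUNDS,
    degree: int = 1,
    sse_mode: str = "cv",
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Choose the LOESS span by bounded scalar (Brent-type) minimization.

    ``sse_mode="cv"`` minimizes 5-fold cross-validated SSE; ``"literal"``
    minimizes training SSE (monotone in span, so it effectively returns the
    lower bound). Ties — within relative 1e-9 — are broken toward the lower
    bound. Falls back to a 0.01-resolution grid search if the scalar
    minimizer fails.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points to optimize the span")
    lo, hi = bounds
    if not (0 < lo <= hi <= 1):
        raise ValueError("span bounds must satisfy 0 < lo <= hi <= 1")
    if lo == hi:
        return float(lo)
    if sse_mode not in ("cv", "literal"):
        raise ValueError("sse_mode must be 'cv' or 'literal'")

    def objective(span: float) -> float:
        span = float(np.clip(span, lo, hi))
        if sse_mode == "cv":
            return _cv_sse(x, y, span, degree, n_folds, seed)
        return _training_sse(x, y, span, degree)

    try:
        res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-3})
        best = float(np.clip(res.x, lo, hi))
        best_obj = float(res.fun)
        if not res.success or not np.isfinite(best_obj):
            raise RuntimeError("scalar minimizer did not converge")
    except (RuntimeError, ValueError):
        logger.warning("optimize_span: scalar minimization failed; grid search fallback")
        grid = np.arange(lo, hi + 1e-12, 0.01)
        vals = [objective(s) for s in grid]
        j = int(np.argmin(vals))
        best, best_obj = float(grid[j]), float(vals[j])

    # tie-break toward the lower bound: a flat objective should not return
    # an arbitrary interior point
    obj_lo = objective(lo)
    if obj_lo <= best_obj * (1 + 1e-9) + 1e-12:
        return float(lo)
    return best


# ---------------------------------------------------------------------------
# Normative model
# ---------------------------------------------------------------------------

@dataclass
class NormativeModel:
    """Per-region spans and one-year age-bin norms.

    ``bins`` columns: region, bin_start (integer year), mean, sd, n,
    retained. Bins are half-open ``[k, k+1)`` intervals.
    """

    spans: pd.Series                  # region -> span
    bins: pd.DataFrame
    min_bin_count: int = MIN_BIN_COUNT
    degree: int = 1
    sse_mode: str = "cv"
    sex: str | None = None

    @property
    def regions(self) -> list[str]:
        return list(self.spans.index)

    def retained_bins(self, region: str) -> pd.DataFrame:
        sel = self.bins[(self.bins["region"] == region) & self.bins["retained"]]
        return sel.set_index("bin_start")

    def lookup_tables(self, regions: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(mean, sd) tables indexed by bin_start with one column per region."""
        ret = self.bins[self.bins["retained"]]
        mean = ret.pivot(index="bin_start", columns="region", values="mean")
        sd = ret.pivot(index="bin_start", columns="region", values="sd")
        return mean.reindex(columns=regions), sd.reindex(columns=regions)

    # -- serialization --------------------------------------------------------

    def save(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.spans.rename("span").rename_axis("region").to_csv(d / "spans.csv")
        self.bins.to_csv(d / "bins.csv", index=False)
        meta = dict(min_bin_count=int(self.min_bin_count), degree=int(self.degree),
                    sse_mode=self.sse_mode, sex=self.sex)
        (d / "meta.yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")

    @classmethod
    def load(cls, directory) -> "NormativeModel":
        from pathlib import Path
        d = Path(directory)
        spans = pd.read_csv(d / "spans.csv", index_col="region")["span"]
        bins = pd.read_csv(d / "bins.csv")
        bins["retained"] = bins["retained"].astype(bool)
        meta = yaml.safe_load((d / "meta.yaml").read_text(encoding="utf-8"))
        return cls(spans=spans, bins=bins, **meta)


def age_bin(age) -> np.ndarray:
    """Integer start of the half-open one-year bin [k, k+1) containing age."""
    return np.floor(np.asarray(age, dtype=float)).astype(int)


def _bin_table(ages: np.ndarray, values: np.ndarray, fitted: np.ndarray,
               min_bin_count: int) -> pd.DataFrame:
    bins = age_bin(ages)
    resid = values - fitted
    rows = []
    for b in range(bins.min(), bins.max() + 1):
        in_bin = bins == b
        nb = int(in_bin.sum())
        if nb == 0:
            continue
        mu = float(np.median(fitted[in_bin]))
        sd = float(np.std(resid[in_bin], ddof=1)) if nb > 1 else 0.0
        retained = nb >= min_bin_count and sd > SD_FLOOR
        rows.append(dict(bin_start=b, mean=mu, sd=sd, n=nb, retained=retained))
    return pd.DataFrame(rows)


def build_region_norms(
    ages: np.ndarray,
    values: np.ndarray,
    span: float | str = "auto",
    min_bin_count: int = MIN_BIN_COUNT,
    span_bounds: tuple[float, float] = SPAN_BOUNDS,
    degree: int = 1,
    sse_mode: str = "cv",
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Fit one region's norms; returns (span, bin table)."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if span == "auto":
        span = optimize_span(ages, values, bounds=span_bounds, degree=degree,
                             sse_mode=sse_mode, seed=seed)
    span = float(span)
    fitted = fit_loess(ages, values, span, degree)
    table = _bin_table(ages, values, fitted, min_bin_count)
    if not table["retained"].any():
        raise ValueError("no retained age bins for this region")
    return span, table


def build_normative_model(
    controls: CohortTable,
    morph: MorphMatrix,
    span: float | str = "auto",
    min_bin_count: int = MIN_BIN_COUNT,
    span_bounds: tuple[float, float] = SPAN_BOUNDS,
    degree: int = 1,
    sse_mode: str = "cv",
    sex: str | None = "male",
    seed: int = 0,
) -> NormativeModel:
    """Estimate age norms for every region from the control group.

    Normative estimation runs on a single declared sex stratum (``sex``,
    pass ``None`` to use all controls as given). Only subjects labelled
    ``control`` are used regardless of what is passed in.
    """
    ctl = controls.subset(controls.df["group"] == "control") \
        if (controls.df["group"] != "control").any() else controls
    if sex is not None:
        ctl = ctl.filter_sex(sex)
    if len(ctl) == 0:
        raise ValueError("no control subjects in the requested stratum")
    ids = ctl.subject_ids
    sub = morph.df.loc[morph.df.index.intersection(ids)]
    ages = ctl.ages_by_id().loc[sub.index].to_numpy()

    spans, tables = {}, []
    for region in morph.regions:
        s, table = build_region_norms(ages, sub[region].to_numpy(), span=span,
                                      min_bin_count=min_bin_count,
                                      span_bounds=span_bounds, degree=degree,
                                      sse_mode=sse_mode, seed=seed)
        spans[region] = s
        table.insert(0, "region", region)
        tables.append(table)
    model = NormativeModel(spans=pd.Series(spans, name="span"),
                           bins=pd.concat(tables, ignore_index=True),
                           min_bin_count=min_bin_count, degree=degree,
                           sse_mode=sse_mode, sex=sex)
    dropped = int((~model.bins["retained"]).sum())
    if dropped:
        logger.info("build_normative_model: %d region-bins dropped (n < %d or sd ~ 0)",
                    dropped, min_bin_count)
    return model


def compute_wscores(
    values: MorphMatrix,
    model: NormativeModel,
    cohort: CohortTable,
) -> pd.DataFrame:
    """Age-normed deviation scores, ``(value - bin_mean) / bin_sd``.

    Returns a subjects x regions frame aligned to ``values``; cells are NaN
    where the subject's age bin was dropped (or lies outside the model).
    """
    regions = values.regions
    missing_regions = [r for r in regions if r not in model.spans.index]
    if missing_regions:
        raise ValueError(f"model lacks regions: {missing_regions[:5]}")
    ages = cohort.ages_by_id()
    ids = values.df.index
    unknown = ids.difference(ages.index)
    if len(unknown):
        raise ValueError(f"subjects without cohort rows: {list(unknown[:5])}")
    bins = age_bin(ages.loc[ids].to_numpy())

    mean_tab, sd_tab = model.lookup_tables(regions)
    mu = mean_tab.reindex(bins).to_numpy()
    sd = sd_tab.reindex(bins).to_numpy()
    w = (values.df.to_numpy() - mu) / sd
    out = pd.DataFrame(w, index=ids, columns=regions)
    n_missing = int(out.isna().sum().sum())
    if n_missing:
        logger.info("compute_wscores: %d subject-region cells missing (dropped bins)",
                    n_missing)
    return out


# ---------------------------------------------------------------------------
# Centile cross-check
# ---------------------------------------------------------------------------

def centile_scores(
    values: MorphMatrix,
    control_cohort: CohortTable,
    control_morph: MorphMatrix,
    cohort: CohortTable,
    min_bin_count: int = MIN_BIN_COUNT,
    to_normal: bool = False,
) -> pd.DataFrame:
    """Empirical within-age-bin percentiles against the control distribution.

    Uses the mid-ECDF convention ``100 * (#less + 0.5 * #equal) / n``,
    clamped to ``[100/(2n), 100 * (1 - 1/(2n))]`` so extremes stay strictly
    inside (0, 100) and map to finite normal quantiles. Bins with fewer
    than ``min_bin_count`` controls yield missing centiles. With
    ``to_normal=True`` percentiles are mapped through the standard normal
    quantile function.
    """
    regions = values.regions
    ctl_ids = control_morph.df.index.intersection(control_cohort.subject_ids)
    ctl_bins = age_bin(control_cohort.ages_by_id().loc[ctl_ids].to_numpy())
    ctl_vals = control_morph.df.loc[ctl_ids]

    subj_bins = age_bin(cohort.ages_by_id().loc[values.df.index].to_numpy())
    out = np.full(values.df.shape, np.nan)
    for b in np.unique(subj_bins):
        ctl_in = ctl_bins == b
        n = int(ctl_in.sum())
        if n < min_bin_count:
            continue
        rows = subj_bins == b
        case_block = values.df.to_numpy()[rows][:, None, :]       # (r, 1, R)
        ctl_block = ctl_vals.to_numpy()[ctl_in][None, :, :]       # (1, n, R)
        less = (ctl_block < case_block).sum(axis=1)
        equal = (ctl_block == case_block).sum(axis=1)
        pct = 100.0 * (less + 0.5 * equal) / n
        pct = np.clip(pct, 100.0 / (2 * n), 100.0 * (1 - 1.0 / (2 * n)))
        out[rows] = pct
    if to_normal:
        out = stats.norm.ppf(out / 100.0)
    return pd.DataFrame(out, index=values.df.index, columns=regions)


# ---------------------------------------------------------------------------
# Bootstrap reliability
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    w: pd.DataFrame        # real w-scores from the full normative sample
    p: pd.DataFrame        # two-sided positional empirical p per subject x region
    q: pd.DataFrame        # BH-FDR across regions, per subject
    n_valid: pd.DataFrame  # resamples contributing per cell
    B: int = 0
    seed: int = 0


def bootstrap_reliability(
    control_cohort: CohortTable,
    control_morph: MorphMatrix,
    target_cohort: CohortTable,
    target_morph: MorphMatrix,
    B: int = 1000,
    seed: int = 0,
    min_bin_count: int = MIN_BIN_COUNT,
    model: NormativeModel | None = None,
    degree: int = 1,
    fdr_q: float = 0.05,
) -> BootstrapResult:
    """Resample the normative sample and locate each real w in its bootstrap
    distribution.

    For each of ``B`` with-replacement resamples of the control group the
    bin norms are rebuilt (at the span already chosen on the full sample)
    and the target subjects re-scored. The empirical p-value is the
    two-sided positional p with the add-one rule,
    ``min(1, 2 * min(#{w* <= w} + 1, #{w* >= w} + 1) / (B_valid + 1))``:
    a real w at the centre of its bootstrap distribution has p ~ 1, one in
    an extreme tail has small p (an unreliable score). Resamples in which
    a subject's bin falls below ``min_bin_count`` contribute missing.
    BH-FDR is applied across regions within each subject.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if model is None:
        model = build_normative_model(control_cohort, control_morph, sex=None,
                                      min_bin_count=min_bin_count, degree=degree)
    regions = target_morph.regions
    w_real = compute_wscores(target_morph, model, target_cohort)

    ctl_ids = control_morph.df.index.intersection(control_cohort.subject_ids)
    ctl_ages = control_cohort.ages_by_id().loc[ctl_ids].to_numpy()
    ctl_vals = control_morph.df.loc[ctl_ids].to_numpy()
    tgt_bins = age_bin(target_cohort.ages_by_id().loc[target_morph.df.index].to_numpy())
    tgt_vals = target_morph.df.to_numpy()
    n_ctl = ctl_ids.size
    spans = model.spans.reindex(regions).to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    wr = w_real.to_numpy()
    n_le = np.zeros(wr.shape, dtype=np.int64)
    n_ge = np.zeros(wr.shape, dtype=np.int64)
    n_valid = np.zeros(wr.shape, dtype=np.int64)

    all_bins = np.arange(age_bin(ctl_ages.min()), age_bin(ctl_ages.max()) + 1)
    bin_pos = {b: i for i, b in enumerate(all_bins)}
    tgt_rows = np.array([bin_pos.get(b, -1) for b in tgt_bins])

    for _ in range(B):
        take = rng.integers(0, n_ctl, size=n_ctl)
        a = ctl_ages[take]
        bins_b = age_bin(a)
        mu_tab = np.full((all_bins.size, len(regions)), np.nan)
        sd_tab = np.full((all_bins.size, len(regions)), np.nan)
        for j, region in enumerate(regions):
            v = ctl_vals[take, j]
            try:
                fitted = fit_loess(a, v, spans[j], degree)
            except ValueError:
                continue
            resid = v - fitted
            for b in np.unique(bins_b):
                in_bin = bins_b == b
                nb = int(in_bin.sum())
                if nb < min_bin_count or b not in bin_pos:
                    continue
                sd = float(np.std(resid[in_bin], ddof=1))
                if sd <= SD_FLOOR:
                    continue
                mu_tab[bin_pos[b], j] = float(np.median(fitted[in_bin]))
                sd_tab[bin_pos[b], j] = sd
        ok_rows = tgt_rows >= 0
        mu = np.full(wr.shape, np.nan)
        sd = np.full(wr.shape, np.nan)
        mu[ok_rows] = mu_tab[tgt_rows[ok_rows]]
        sd[ok_rows] = sd_tab[tgt_rows[ok_rows]]
        w_star = (tgt_vals - mu) / sd
        valid = np.isfinite(w_star) & np.isfinite(wr)
        n_le += valid & (w_star <= wr)
        n_ge += valid & (w_star >= wr)
        n_valid += valid

    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * np.minimum(n_le + 1, n_ge + 1) / (n_valid + 1)
    p = np.minimum(p, 1.0)
    p[n_valid == 0] = np.nan
    p_df = pd.DataFrame(p, index=w_real.index, columns=regions)

    q = np.full(p.shape, np.nan)
    for i in range(p.shape[0]):
        row = p[i]
        ok = np.isfinite(row)
        if ok.any():
            q[i, ok] = bh_fdr(row[ok])[0]
    q_df = pd.DataFrame(q, index=w_real.index, columns=regions)
    return BootstrapResult(w=w_real, p=p_df, q=q_df,
                           n_valid=pd.DataFrame(n_valid, index=w_real.index,
                                                columns=regions),
                           B=B, seed=seed)
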