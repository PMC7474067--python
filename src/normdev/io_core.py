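"""Data model, table I/O, cohort matching and quality-control exclusions.

Tables are UTF-8 delimited text (comma by default, tab accepted) with a
period decimal separator only. Rows that fail validation are collected in a
:class:`RejectionReport` rather than raised one at a time, so a load either
succeeds with a full accounting of what was dropped or fails loudly on
structural problems (missing columns, duplicate ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")
SEX_LABELS = ("male", "female")

#: default accepted age range in years
DEFAULT_AGE_RANGE = (5.0, 65.0)

COHORT_COLUMNS = ("subject_id", "group", "sex", "age", "site", "motion_fd", "euler")
REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "sex", "age", "site")


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class ValidationError(ValueError):
    """Table content violates a structural invariant (e.g. duplicate ids)."""


@dataclass(frozen=True)
class RejectionReport:
    """Per-row rejections recorded during a load.

    ``rows`` has columns ``row`` (0-based data row index), ``subject_id``
    (when parseable) and ``reason``.
    """

    rows: pd.DataFrame

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.rows)

    @property
    def empty(self) -> bool:
        return self.rows.empty

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: list[dict]) -> "RejectionReport":
        return cls(pd.DataFrame(records, columns=["row", "subject_id", "reason"]))


@dataclass(frozen=True)
class CohortTable:
    """Validated per-subject demographics and QC covariates.

    ``df`` columns: subject_id (unique str), group ({case, control}),
    sex ({male, female}), age (years, finite, within ``age_range``),
    site (str label), motion_fd (mm, >=0 or NaN), euler (>=0 or NaN).
    """

    df: pd.DataFrame
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing required columns: {missing}")
        dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
        if len(dupes):
            raise ValidationError(f"duplicate subject_id values: {sorted(map(str, dupes))}")
        bad_group = set(df["group"].unique()) - set(GROUP_LABELS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(df["sex"].unique()) - set(SEX_LABELS)
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        age = df["age"].to_numpy(dtype=float)
        lo, hi = self.age_range
        if not np.all(np.isfinite(age)) or (age < lo).any() or (age > hi).any():
            raise ValidationError(f"age values outside declared range [{lo}, {hi}]")
        if df["site"].isna().any() or (df["site"].astype(str) == "").any():
            raise ValidationError("every subject must have a site label")

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> pd.Index:
        return pd.Index(self.df["subject_id"])

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[mask].reset_index(drop=True), self.age_range)

    def filter_group(self, group: str) -> "CohortTable":
        if group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}")
        return self.subset(self.df["group"] == group)

    def filter_sex(self, sex: str) -> "CohortTable":
        if sex not in SEX_LABELS:
            raise ValueError(f"sex must be one of {SEX_LABELS}")
        return self.subset(self.df["sex"] == sex)

    def ages_by_id(self) -> pd.Series:
        return self.df.set_index("subject_id")["age"]

    def to_csv(self, path, sep: str = ",") -> None:
        self.df.to_csv(path, index=False, sep=sep)


@dataclass(frozen=True)
class MorphMatrix:
    """Subjects x regions matrix of one morphometric (thickness, mm).

    ``df`` is indexed by subject_id with one float column per region; all
    cells finite and strictly positive.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals <= 0).any():
            raise ValidationError("morphometry values must be finite and > 0")
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate subject_id rows in morphometry matrix")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def regions(self) -> list[str]:
        return list(self.df.columns)

    @property
    def subject_ids(self) -> pd.Index:
        return self.df.index

    def subset(self, subject_ids) -> "MorphMatrix":
        return MorphMatrix(self.df.loc[subject_ids])

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.df.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(path, index=False, sep=sep)


@dataclass
class MatchResult:
    cases: CohortTable
    controls: CohortTable
    pairs: pd.DataFrame  # case_id, control_id, age_case, age_control
    mean_abs_age_diff: float = field(default=np.nan)


def _read_table(path, sep) -> pd.DataFrame:
    # dtype=str: parse numerics ourselves so bad cells become row rejections,
    # and the strict period-decimal dialect is enforced (no locale fallback).
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _parse_float(raw: str | float) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s == "" or s.lower() in ("na", "nan"):
        return np.nan
    if "," in s:
        raise ValueError(f"comma decimal separator not accepted: {s!r}")
    return float(s)


def load_cohort(
    path,
    schema: dict[str, str] | None = None,
    sep: str = ",",
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> tuple[CohortTable, RejectionReport]:
    """Load and validate a cohort table from delimited text.

    Parameters
    ----------
    path : str or file-like
        CSV/TSV file with a header row.
    schema : dict, optional
        Map from canonical column name (``subject_id``, ``group``, ...) to
        the column name used in the file. Identity by default.
    sep : str
        Field delimiter, ``","`` or ``"\\t"``.
    age_range : (float, float)
        Declared study age range; rows outside it are rejected.

    Returns
    -------
    (CohortTable, RejectionReport)

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If subject ids are duplicated among the accepted rows.
    """
    raw = _read_table(path, sep)
    schema = schema or {}
    colmap = {canon: schema.get(canon, canon) for canon in COHORT_COLUMNS}
    missing = [src for canon, src in colmap.items()
               if canon in REQUIRED_COHORT_COLUMNS and src not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    records, rejects = [], []
    for i, row in raw.iterrows():
        sid = str(row[colmap["subject_id"]]).strip()
        try:
            age = _parse_float(row[colmap["age"]])
            if not np.isfinite(age):
                raise ValueError("age missing or non-finite")
            if not (age_range[0] <= age <= age_range[1]):
                raise ValueError(f"age {age} outside range {age_range}")
            group = str(row[colmap["group"]]).strip().lower()
            if group not in GROUP_LABELS:
                raise ValueError(f"unknown group label {group!r}")
            sex = str(row[colmap["sex"]]).strip().lower()
            if sex not in SEX_LABELS:
                raise ValueError(f"unknown sex label {sex!r}")
            site = str(row[colmap["site"]]).strip()
            if site == "" or site.lower() == "nan":
                raise ValueError("missing site label")
            fd_col, eu_col = colmap["motion_fd"], colmap["euler"]
            fd = _parse_float(row[fd_col]) if fd_col in raw.columns else np.nan
            eu = _parse_float(row[eu_col]) if eu_col in raw.columns else np.nan
            if np.isfinite(fd) and fd < 0:
                raise ValueError("motion_fd must be >= 0")
            if np.isfinite(eu) and eu < 0:
                raise ValueError("euler must be >= 0")
        except ValueError as exc:
            rejects.append({"row": int(i), "subject_id": sid, "reason": str(exc)})
            continue
        records.append(dict(subject_id=sid, group=group, sex=sex, age=age,
                            site=site, motion_fd=fd, euler=eu))

    report = RejectionReport.from_records(rejects)
    if not report.empty:
        logger.info("load_cohort: rejected %d rows", len(report))
    df = pd.DataFrame(records, columns=list(COHORT_COLUMNS))
    return CohortTable(df, age_range), report


def load_morphometry(
    path,
    region_list: list[str] | None = None,
    sep: str = ",",
) -> tuple[MorphMatrix, RejectionReport]:
    """Load a subjects x regions morphometry matrix from delimited text.

    The file must have a ``subject_id`` column plus one numeric column per
    region. Columns not in ``region_list`` are dropped with a warning;
    regions listed but absent raise :class:`SchemaError`. Rows with
    non-numeric, non-finite or non-positive cells are rejected.
    """
    raw = _read_table(path, sep)
    if "subject_id" not in raw.columns:
        raise SchemaError("morphometry file must contain a subject_id column")
    file_regions = [c for c in raw.columns if c != "subject_id"]
    if region_list is None:
        regions = file_regions
    else:
        missing = [r for r in region_list if r not in file_regions]
        if missing:
            raise SchemaError(f"regions absent from file: {missing}")
        extra = [c for c in file_regions if c not in region_list]
        if extra:
            logger.warning("load_morphometry: dropping %d unknown region columns: %s",
                           len(extra), extra[:10])
        regions = list(region_list)

    rows, index, rejects = [], [], []
    for i, row in raw.iterrows():
        sid = str(row["subject_id"]).strip()
        try:
            vals = np.array([_parse_float(row[r]) for r in regions], dtype=float)
        except ValueError as exc:
            rejects.append({"row": int(i), "subject_id": sid, "reason": str(exc)})
            continue
        if not np.all(np.isfinite(vals)):
            rejects.append({"row": int(i), "subject_id": sid, "reason": "missing cell"})
            continue
        if (vals <= 0).any():
            rejects.append({"row": int(i), "subject_id": sid,
                            "reason": "non-positive morphometry value"})
            continue
        rows.append(vals)
        index.append(sid)

    report = RejectionReport.from_records(rejects)
    if not report.empty:
        logger.info("load_morphometry: rejected %d rows", len(report))
    df = pd.DataFrame(np.array(rows).reshape(len(rows), len(regions)),
                      index=pd.Index(index, name="subject_id"), columns=regions)
    return MorphMatrix(df), report


def read_region_list(path) -> list[str]:
    """Read a plain-text region list, one label per line, blank lines skipped."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def match_groups_by_age(cases: CohortTable, controls: CohortTable) -> MatchResult:
    """Greedy 1:1 nearest-neighbour age matching without replacement.

    Cases are traversed in descending age order; each is paired with the
    unmatched control of nearest age, ties broken toward the younger
    control. Output groups have equal size min(n_cases, n_controls).
    """
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty for matching")

    case_df = cases.df.sort_values("age", ascending=False, kind="mergesort")
    ctrl_age = controls.df["age"].to_numpy(dtype=float)
    # stable order: ascending age so argmin on ties picks the younger control
    order = np.argsort(ctrl_age, kind="mergesort")
    avail_idx = list(order)

    pairs = []
    for _, case in case_df.iterrows():
        if not avail_idx:
            break
        diffs = np.abs(ctrl_age[avail_idx] - case["age"])
        j = int(np.argmin(diffs))  # first minimum = youngest on ties
        ctrl_pos = avail_idx.pop(j)
        ctrl = controls.df.iloc[ctrl_pos]
        pairs.append(dict(case_id=case["subject_id"], control_id=ctrl["subject_id"],
                          age_case=case["age"], age_control=ctrl["age"]))

    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "age_case", "age_control"])
    mean_diff = float(np.mean(np.abs(pairs_df["age_case"] - pairs_df["age_control"]))) \
        if len(pairs_df) else np.nan

    matched_cases = cases.subset(cases.df["subject_id"].isin(pairs_df["case_id"]))
    matched_ctrls = controls.subset(controls.df["subject_id"].isin(pairs_df["control_id"]))
    logger.info("match_groups_by_age: %d pairs, mean |age diff| = %.3f years",
                len(pairs_df), mean_diff)
    return MatchResult(matched_cases, matched_ctrls, pairs_df, mean_diff)


@dataclass
class EulerExclusion:
    kept: CohortTable
    excluded_ids: list[str]
    threshold: float
    n_ties_kept: int
    n_missing: int


def qc_exclude_euler(cohort: CohortTable, top_fraction: float = 0.10) -> EulerExclusion:
    """Exclude the worst ``top_fraction`` of subjects by Euler index.

    With k = floor(n * top_fraction), the threshold is the (n-k)-th order
    statistic of the observed euler values and subjects strictly above it
    are removed; subjects exactly at the threshold are kept (ties retained
    conservatively). Subjects with missing euler are kept and counted.
    """
    if not (0 <= top_fraction < 1):
        raise ValueError("top_fraction must be in [0, 1)")
    euler = cohort.df["euler"].to_numpy(dtype=float)
    observed = euler[np.isfinite(euler)]
    if observed.size == 0:
        raise ValueError("all euler values missing; cannot apply QC exclusion")
    n_missing = int(np.sum(~np.isfinite(euler)))

    n = observed.size
    k = int(np.floor(n * top_fraction))
    if k == 0:
        return EulerExclusion(cohort, [], float(np.max(observed)), 0, n_missing)
    threshold = float(np.sort(observed)[n - k - 1] if k < n else np.min(observed))
    drop = np.isfinite(euler) & (euler > threshold)
    ties = int(np.sum(np.isfinite(euler) & (euler == threshold)))
    excluded = cohort.df.loc[drop, "subject_id"].tolist()
    kept = cohort.subset(~drop)
    logger.info("qc_exclude_euler: excluded %d subjects above euler %.6g "
                "(%d at-threshold ties kept, %d missing euler retained)",
                len(excluded), threshold, ties, n_missing)
    return EulerExclusion(kept, excluded, threshold, ties, n_missing)
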