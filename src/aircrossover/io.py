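"""Tabular I/O, ICD-10 category mapping, and run configuration.

Visit-count files are tidy CSV (``date,sex,age_group,category,count``) or,
alternatively, carry an ``icd10`` column that is mapped onto the seven
disorder categories before aggregation.  Daily exposure files are CSV with
columns ``date,no2_ppb,o3_ppb_max8h,pm25_ugm3,temp_c[,aqhi]``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import re
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .datasets import AGE_GROUPS, CATEGORIES

logger = logging.getLogger(__name__)

SEXES = ("M", "F")

__all__ = [
    "DisorderCategoryMap",
    "DEFAULT_CATEGORY_MAP",
    "RunConfig",
    "read_visit_counts",
    "write_visit_counts",
    "read_daily_exposures",
    "write_daily_exposures",
    "aggregate_totals",
    "study_period_days",
]


class DisorderCategoryMap:
    """Map ICD-10 codes onto the seven mental-disorder categories.

    The default mapping follows the standard ICD-10 chapter blocks:
    F00-F09 organic, F10-F19 substance-related, F20-F29 schizophrenic and
    psychotic, F30-F39 mood, F40-F48 anxiety, F60-F69 personality; the
    remaining F-chapter blocks plus intentional self-harm (X60-X84) fall in
    "other".  Codes outside every configured block are routed to "other" and
    logged.  A replacement map can be loaded from a two-column CSV
    (``icd10_prefix,category``).
    """

    _CODE_RE = re.compile(r"^([A-Z])(\d{2})")

    def __init__(self, ranges: Sequence[tuple[str, str, str]] | None = None):
        # ranges: (first_prefix, last_prefix, category), inclusive, e.g. ("F00","F09","organic")
        if ranges is None:
            ranges = [
                ("F00", "F09", "organic"),
                ("F10", "F19", "substance_related"),
                ("F20", "F29", "schizophrenic_psychotic"),
                ("F30", "F39", "mood"),
                ("F40", "F48", "anxiety"),
                ("F60", "F69", "personality"),
                ("F50", "F59", "other"),
                ("F70", "F99", "other"),
                ("X60", "X84", "other"),
            ]
        self.ranges = list(ranges)
        cats = {c for _, _, c in self.ranges}
        unknown = cats - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in map: {sorted(unknown)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DisorderCategoryMap":
        df = pd.read_csv(path)
        ranges = []
        for _, row in df.iterrows():
            prefix = str(row["icd10_prefix"]).strip().upper()
            if "-" in prefix:
                lo, hi = prefix.split("-", 1)
            else:
                lo = hi = prefix
            ranges.append((lo, hi, str(row["category"]).strip()))
        return cls(ranges)

    def category(self, code: str) -> str:
        """Category for one ICD-10 code; unmapped codes go to ``other``."""
        m = self._CODE_RE.match(str(code).strip().upper())
        if m:
            prefix = m.group(1) + m.group(2)
            for lo, hi, cat in self.ranges:
                if lo[0] == prefix[0] and lo <= prefix <= hi:
                    return cat
        logger.warning("ICD-10 code %r not covered by the category map; routed to 'other'", code)
        return "other"


DEFAULT_CATEGORY_MAP = DisorderCategoryMap()


def study_period_days(start: dt.date, end: dt.date) -> int:
    """Inclusive number of calendar days between two dates (leap-aware)."""
    start, end = _as_date(start), _as_date(end)
    if start > end:
        raise ValueError(f"study start {start} is after study end {end}")
    return (end - start).days + 1


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def read_visit_counts(
    path: str | Path,
    category_map: DisorderCategoryMap | None = None,
    study_start: dt.date | None = None,
    study_end: dt.date | None = None,
) -> pd.DataFrame:
    """Read a visit-count CSV into the canonical tidy table.

    The file needs columns ``date,sex,age_group,count`` plus either
    ``category`` or ``icd10`` (the latter is mapped through *category_map*,
    default :data:`DEFAULT_CATEGORY_MAP`).  Rows sharing a
    (date, sex, age_group, category) key are summed.  Malformed dates or
    negative counts are rejected with the offending row index.
    """
    df = pd.read_csv(path, dtype={"sex": str, "age_group": str})
    required = {"date", "sex", "age_group", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: no visit rows (header only)", path)
        return pd.DataFrame(columns=["date", "sex", "age_group", "category", "count"])

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = dates.isna()
    if bad.any():
        raise ValueError(f"{path}: unparseable date at row index {int(bad.idxmax())}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        raise ValueError(f"{path}: invalid count at row index {int(bad.idxmax())}")

    out = df.copy()
    out["date"] = dates.dt.normalize()
    out["count"] = counts.astype(int)
    if "category" not in out.columns:
        if "icd10" not in out.columns:
            raise ValueError(f"{path}: needs a 'category' or 'icd10' column")
        cmap = category_map or DEFAULT_CATEGORY_MAP
        out["category"] = [cmap.category(c) for c in out["icd10"]]
    _validate_levels(out)
    if study_start is not None or study_end is not None:
        lo = pd.Timestamp(_as_date(study_start)) if study_start else out["date"].min()
        hi = pd.Timestamp(_as_date(study_end)) if study_end else out["date"].max()
        outside = (out["date"] < lo) | (out["date"] > hi)
        if outside.any():
            raise ValueError(
                f"{path}: {int(outside.sum())} rows dated outside the study period {lo.date()}..{hi.date()}"
            )
    out = (
        out.groupby(["date", "sex", "age_group", "category"], as_index=False, observed=True)["count"]
        .sum()
        .sort_values(["date", "sex", "age_group", "category"], ignore_index=True)
    )
    return out


def _validate_levels(df: pd.DataFrame) -> None:
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex levels {sorted(bad_sex)}; expected {SEXES}")
    bad_age = set(df["age_group"].unique()) - set(AGE_GROUPS)
    if bad_age:
        raise ValueError(f"unknown age groups {sorted(bad_age)}; expected {AGE_GROUPS}")
    bad_cat = set(df["category"].unique()) - set(CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown categories {sorted(bad_cat)}")


def write_visit_counts(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def aggregate_totals(table: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame | int:
    """Marginal visit totals over the requested dimensions.

    With empty *by*, returns the grand total as an ``int``; otherwise a
    DataFrame of summed counts per group.  Marginals over any partition sum to
    the same grand total.
    """
    allowed = {"date", "sex", "age_group", "category"}
    unknown = set(by) - allowed
    if unknown:
        raise KeyError(f"unknown grouping keys {sorted(unknown)}; allowed {sorted(allowed)}")
    if not by:
        return int(table["count"].sum())
    return table.groupby(list(by), as_index=False, observed=True)["count"].sum()


def read_daily_exposures(path: str | Path) -> pd.DataFrame:
    """Read a daily exposure CSV into a date-indexed frame (daily frequency)."""
    df = pd.read_csv(path, parse_dates=["date"])
    df = df.set_index("date").sort_index()
    full = pd.date_range(df.index.min(), df.index.max(), freq="D")
    return df.reindex(full).rename_axis("date")


def write_daily_exposures(daily: pd.DataFrame, path: str | Path) -> None:
    out = daily.copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.rename_axis("date").to_csv(path, float_format="%.6g")


_DEFAULTS = dict(
    study_start=dt.date(2004, 4, 1),
    study_end=dt.date(2015, 12, 31),
    lags=tuple(range(6)),
    pollutants=("no2", "o3", "pm25"),
    spline_df=3,
    rng_seed=20040401,
)


@dataclasses.dataclass
class RunConfig:
    """Run configuration for the pipeline; YAML-serialisable.

    Defaults follow the Toronto study set-up: study period 1 Apr 2004 --
    31 Dec 2015 (4292 days), single-pollutant models for NO2, daily-maximum
    8-h O3 and PM2.5 at lags 0-5, temperature as a natural spline with three
    degrees of freedom, and the AQHI as the multi-pollutant sensitivity
    exposure.
    """

    study_start: dt.date = _DEFAULTS["study_start"]
    study_end: dt.date = _DEFAULTS["study_end"]
    lags: Sequence[int] = _DEFAULTS["lags"]
    pollutants: Sequence[str] = _DEFAULTS["pollutants"]
    spline_df: int = _DEFAULTS["spline_df"]
    subgroups: str = "default"  # "default" | "overall" | "sex_age" | "category"
    rng_seed: int = _DEFAULTS["rng_seed"]
    visits_path: str | None = None
    exposures_path: str | None = None
    output_dir: str = "results"

    def __post_init__(self):
        self.study_start = _as_date(self.study_start)
        self.study_end = _as_date(self.study_end)
        self.lags = tuple(int(k) for k in self.lags)
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if any(k < 0 for k in self.lags):
            raise ValueError("lags must be non-negative")
        if self.spline_df < 1:
            raise ValueError("spline_df must be >= 1")
        known = {"no2", "o3", "pm25", "aqhi"}
        bad = set(self.pollutants) - known
        if bad:
            raise ValueError(f"unknown pollutants {sorted(bad)}; allowed {sorted(known)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["study_start"] = self.study_start.isoformat()
        data["study_end"] = self.study_end.isoformat()
        data["lags"] = list(self.lags)
        data["pollutants"] = list(self.pollutants)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @property
    def n_days(self) -> int:
        return study_period_days(self.study_start, self.study_end)
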