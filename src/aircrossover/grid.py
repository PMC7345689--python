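"""Run the full subgroup x pollutant x lag analysis grid.

One conditional quasi-Poisson fit per cell of the requested grid, each
reported as a relative risk per one interquartile-range increase of the
pollutant; plus the 0/1 significance map (1 iff the lower 95% confidence
limit exceeds 1), the split-period sensitivity analysis, and the AQHI
multi-pollutant sensitivity.  Per-cell confidence intervals are unadjusted
for multiple testing, matching common practice in this literature — the map
is a screening display, not a family-wise inference.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import AGE_GROUPS, CATEGORIES
from .exposure import compute_aqhi, interquartile_range
from .model import ConditionalPoissonModel
from .strata import stratum_labels

logger = logging.getLogger(__name__)

__all__ = [
    "Subgroup",
    "GridSpec",
    "run_grid",
    "significance_map",
    "sensitivity_split",
    "aqhi_sensitivity",
    "write_results",
    "plot_significance_map",
]

POLLUTANT_COLUMNS = {"no2": "no2_ppb", "o3": "o3_ppb_max8h", "pm25": "pm25_ugm3", "aqhi": "aqhi"}

RESULT_COLUMNS = [
    "subgroup", "sex", "age_group", "category", "pollutant", "lag",
    "beta", "se_beta", "p", "rr", "rr_low", "rr_high",
    "n_days", "n_strata", "phi", "status",
]


@dataclasses.dataclass(frozen=True)
class Subgroup:
    """Selector over the visit table; ``None`` marginalises a dimension."""

    sex: str | None = None
    age_group: str | None = None
    category: str | None = None

    @property
    def label(self) -> str:
        if self.category:
            return f"{self.category}:{self.sex or 'A'}"
        if self.sex and self.age_group:
            return f"{self.sex}[{self.age_group}]"
        return self.sex or "All"

    def select(self, visits: pd.DataFrame) -> pd.DataFrame:
        out = visits
        for field in ("sex", "age_group", "category"):
            want = getattr(self, field)
            if want is not None:
                out = out[out[field] == want]
        return out


def _overall() -> list[Subgroup]:
    return [Subgroup(), Subgroup(sex="M"), Subgroup(sex="F")]


def _sex_age() -> list[Subgroup]:
    return [Subgroup(sex=s, age_group=a) for s in ("M", "F") for a in AGE_GROUPS]


def _category_amf() -> list[Subgroup]:
    return [Subgroup(sex=s, category=c) for c in CATEGORIES for s in (None, "M", "F")]


@dataclasses.dataclass
class GridSpec:
    """Which subgroups, pollutants and lags to fit, and the spline df."""

    subgroups: Sequence[Subgroup]
    pollutants: Sequence[str] = ("no2", "o3", "pm25")
    lags: Sequence[int] = tuple(range(6))
    spline_df: int = 3

    def __post_init__(self):
        if not self.subgroups or not self.pollutants or not len(self.lags):
            raise ValueError("subgroups, pollutants and lags must be non-empty")
        unknown = set(self.pollutants) - set(POLLUTANT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown pollutants {sorted(unknown)}")

    @classmethod
    def default(cls, **kw) -> "GridSpec":
        """The full reporting grid: overall A/M/F, sex x age, category x A/M/F."""
        return cls(subgroups=_overall() + _sex_age() + _category_amf(), **kw)

    @classmethod
    def overall(cls, **kw) -> "GridSpec":
        return cls(subgroups=_overall(), **kw)

    @classmethod
    def sex_age(cls, **kw) -> "GridSpec":
        return cls(subgroups=_sex_age(), **kw)

    @classmethod
    def categories(cls, **kw) -> "GridSpec":
        return cls(subgroups=_category_amf(), **kw)


def _ensure_aqhi(exposures: pd.DataFrame) -> pd.DataFrame:
    if "aqhi" not in exposures.columns:
        exposures = exposures.copy()
        exposures["aqhi"] = compute_aqhi(
            exposures["no2_ppb"].to_numpy(),
            exposures["o3_ppb_max8h"].to_numpy(),
            exposures["pm25_ugm3"].to_numpy(),
        )
    return exposures


def _daily_counts(visits: pd.DataFrame, subgroup: Subgroup, index: pd.DatetimeIndex) -> np.ndarray:
    sel = subgroup.select(visits)
    daily = sel.groupby(pd.to_datetime(sel["date"]).dt.normalize())["count"].sum()
    return daily.reindex(index, fill_value=0).to_numpy(dtype=float)


def run_grid(
    visits: pd.DataFrame,
    exposures: pd.DataFrame,
    spec: GridSpec,
    study_start=None,
    study_end=None,
) -> pd.DataFrame:
    """Fit every (subgroup, pollutant, lag) cell and collect risk estimates.

    Returns one row per requested cell; cells that cannot be fitted carry the
    failure reason in ``status`` and missing estimates, so the grid output
    always has ``len(subgroups) * len(pollutants) * len(lags)`` rows.
    IQR scaling constants are computed per pollutant over the analysis-period
    days.  Output is a pure function of the inputs (re-runs are identical).
    """
    exposures = _ensure_aqhi(exposures.sort_index())
    if study_start is not None:
        exposures = exposures.loc[pd.Timestamp(study_start):]
    if study_end is not None:
        exposures = exposures.loc[:pd.Timestamp(study_end)]
    index = exposures.index
    strata = stratum_labels(index).to_numpy()
    temp = exposures["temp_c"].to_numpy(dtype=float) if "temp_c" in exposures else None

    iqrs = {
        pol: interquartile_range(exposures[POLLUTANT_COLUMNS[pol]], pollutant=pol)
        for pol in spec.pollutants
    }
    lagged = {
        (pol, lag): exposures[POLLUTANT_COLUMNS[pol]].shift(lag).to_numpy(dtype=float)
        for pol in spec.pollutants
        for lag in spec.lags
    }
    temp_lagged = {
        lag: (None if temp is None else exposures["temp_c"].shift(lag).to_numpy(dtype=float))
        for lag in spec.lags
    }

    rows = []
    for subgroup in spec.subgroups:
        counts = _daily_counts(visits, subgroup, index)
        base = {
            "subgroup": subgroup.label,
            "sex": subgroup.sex or "A",
            "age_group": subgroup.age_group or "all",
            "category": subgroup.category or "all",
        }
        empty = counts.sum() == 0
        if empty:
            logger.warning("subgroup %s has zero counts on every day; skipped", subgroup.label)
        for pol in spec.pollutants:
            for lag in spec.lags:
                row = dict(base, pollutant=pol, lag=lag)
                if empty:
                    row["status"] = "empty_subgroup"
                    rows.append(row)
                    continue
                try:
                    model = ConditionalPoissonModel(
                        counts,
                        lagged[(pol, lag)],
                        strata,
                        temperature=temp_lagged[lag],
                        spline_df=spec.spline_df,
                        exposure_name=pol,
                    )
                    res = model.fit()
                    if not res.converged:
                        raise ValueError("did not converge")
                    est = res.rr_per_iqr(iqrs[pol], lag=lag, subgroup=subgroup.label)
                except (ValueError, np.linalg.LinAlgError) as err:
                    logger.warning("cell %s/%s/lag%d failed: %s", subgroup.label, pol, lag, err)
                    row["status"] = f"failed: {err}"
                    rows.append(row)
                    continue
                row.update(res.to_row())
                row.update(rr=est.rr, rr_low=est.ci_low, rr_high=est.ci_high, status="ok")
                rows.append(row)
    out = pd.DataFrame(rows).reindex(columns=RESULT_COLUMNS)
    return out


def significance_map(results: pd.DataFrame) -> pd.DataFrame:
    """0/1 map of positive statistically significant cells.

    Entry 1 iff the estimate's lower 95% confidence limit strictly exceeds 1;
    failed or missing cells are 0.  Rows are (subgroup, pollutant), columns
    are lags.
    """
    flagged = ((results["rr_low"] > 1.0) & (results["status"] == "ok")).astype(int)
    tab = results.assign(flag=flagged).pivot_table(
        index=["subgroup", "pollutant"], columns="lag", values="flag",
        aggfunc="max", fill_value=0, observed=True,
    )
    return tab.astype(int)


def sensitivity_split(
    visits: pd.DataFrame,
    exposures: pd.DataFrame,
    cutpoint,
    spec: GridSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Halve the study period at *cutpoint* and re-run the grid in each half.

    The second interval starts at *cutpoint*; strata are rebuilt from
    scratch inside each interval, so no stratum spans the cut.  Returns the
    two result frames and a paired comparison with the standardised
    difference of the two slopes (``z_diff``).
    """
    cut = pd.Timestamp(cutpoint)
    if not (exposures.index.min() < cut <= exposures.index.max()):
        raise ValueError("cutpoint must fall inside the study period")
    dates = pd.to_datetime(visits["date"])
    first = run_grid(visits[dates < cut], exposures.loc[: cut - pd.Timedelta(days=1)], spec)
    second = run_grid(visits[dates >= cut], exposures.loc[cut:], spec)
    keys = ["subgroup", "sex", "age_group", "category", "pollutant", "lag"]
    comparison = first.merge(second, on=keys, suffixes=("_1", "_2"))
    comparison["z_diff"] = (comparison["beta_1"] - comparison["beta_2"]) / np.sqrt(
        comparison["se_beta_1"] ** 2 + comparison["se_beta_2"] ** 2
    )
    return first, second, comparison


def aqhi_sensitivity(visits: pd.DataFrame, exposures: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """The multi-pollutant sensitivity: the same grid with AQHI as exposure."""
    aqhi_spec = dataclasses.replace(spec, pollutants=("aqhi",))
    return run_grid(visits, _ensure_aqhi(exposures), aqhi_spec)


def write_results(results: pd.DataFrame, outdir) -> dict[str, Path]:
    """Write the results files, split by reporting family.

    ``ResAll.csv`` carries the overall all/male/female rows, ``ResAgeGSex.csv``
    the sex-by-age-group rows, and ``ResTypeAMF.csv`` the disorder-category
    rows (all/male/female); ``results.csv`` holds every cell and
    ``significance_map.csv`` the 0/1 map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    overall = results[(results["age_group"] == "all") & (results["category"] == "all")]
    by_age = results[(results["age_group"] != "all") & (results["category"] == "all")]
    by_cat = results[results["category"] != "all"]
    paths = {}
    for name, frame in (
        ("ResAll", overall),
        ("ResAgeGSex", by_age),
        ("ResTypeAMF", by_cat),
        ("results", results),
    ):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path
    sig = significance_map(results)
    path = outdir / "significance_map.csv"
    sig.to_csv(path)
    paths["significance_map"] = path
    return paths


def plot_significance_map(sigmap: pd.DataFrame, path=None):
    """Heat-map rendering of the 0/1 significance map (red = significant)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * sigmap.shape[1], 1 + 0.28 * sigmap.shape[0])
    )
    ax.imshow(sigmap.to_numpy(), cmap="Reds", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(sigmap.shape[1]), [str(c) for c in sigmap.columns])
    ax.set_yticks(range(sigmap.shape[0]), [" / ".join(map(str, i)) for i in sigmap.index])
    ax.set_xlabel("lag (days)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
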