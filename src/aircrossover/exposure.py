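"""Daily exposure metrics from hourly multi-monitor measurements.

The daily metrics mirror standard regulatory conventions for short-term
air-pollution time-series work: per-hour averaging across monitors followed by
a daily mean (NO2, PM2.5, temperature) or the daily maximum of 8-hour rolling
means (ozone), the Canadian Air Quality Health Index (AQHI) combining the
three pollutants, lagged copies of each daily series, and the interquartile
range used to scale relative risks.

Daily series are represented as :class:`pandas.Series` with a daily
``DatetimeIndex``; missing days are ``NaN``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "AqhiCoefficients",
    "AQHI_COEFFICIENTS",
    "ScalingSpec",
    "read_hourly_panel",
    "daily_mean_across_monitors",
    "daily_max_8h",
    "compute_aqhi",
    "lag_series",
    "interquartile_range",
    "build_daily_table",
]


@dataclasses.dataclass(frozen=True)
class AqhiCoefficients:
    """Fixed excess-risk coefficients of Canada's AQHI.

    Per-ppb coefficients for NO2 and O3, per-(ug/m3) for PM2.5, and the
    overall scale 1000/10.4 that maps the summed excess risks onto the
    familiar 1-10+ index range.
    """

    c_no2: float = 0.000871
    c_o3: float = 0.000537
    c_pm25: float = 0.000487
    scale: float = 1000.0 / 10.4


AQHI_COEFFICIENTS = AqhiCoefficients()


@dataclasses.dataclass(frozen=True)
class ScalingSpec:
    """IQR scaling constant for one pollutant, with the quantile convention used."""

    pollutant: str
    iqr: float
    quantile_method: str = "linear"

    def __post_init__(self):
        if self.iqr < 0:
            raise ValueError("IQR cannot be negative")


def read_hourly_panel(path) -> pd.DataFrame:
    """Read an hourly panel CSV (``date,hour,monitor_id,pollutant,value``)."""
    df = pd.read_csv(path, parse_dates=["date"], dtype={"monitor_id": str})
    if not df["hour"].between(0, 23).all():
        raise ValueError("hour outside 0..23")
    if (df["value"].dropna() < 0).any():
        raise ValueError("negative concentration value")
    dup = df.duplicated(["date", "hour", "monitor_id", "pollutant"])
    if dup.any():
        raise ValueError("duplicate (date, hour, monitor, pollutant) measurement")
    return df


def _hourly_monitor_mean(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-hour mean across reporting monitors, as a (date x hour) matrix."""
    if panel.empty:
        raise ValueError("empty hourly panel")
    hourly = panel.groupby([panel["date"].dt.normalize(), "hour"])["value"].mean()
    mat = hourly.unstack("hour")
    full_days = pd.date_range(mat.index.min(), mat.index.max(), freq="D")
    return mat.reindex(index=full_days, columns=range(24))


def daily_mean_across_monitors(panel: pd.DataFrame, completeness: float = 0.75) -> pd.Series:
    """Daily mean concentration: monitors averaged per hour, hours averaged per day.

    A day is reported only if at least ``completeness * 24`` hourly values are
    present after monitor averaging (default 18 of 24); otherwise it is
    missing.  Averaging across monitors first makes the metric robust to
    monitors with different missingness patterns.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    mat = _hourly_monitor_mean(panel)
    n_present = mat.notna().sum(axis=1)
    daily = mat.mean(axis=1)
    daily[n_present < completeness * 24] = np.nan
    return daily.rename("daily_mean")


def daily_max_8h(hourly: pd.DataFrame | pd.Series, min_hours_in_window: int = 6) -> pd.Series:
    """Daily maximum 8-hour mean (the regulatory ozone metric).

    *hourly* is either an hourly panel (monitor-averaged internally) or a
    (date x hour) matrix / multi-indexed series.  For each day the means of
    the 17 within-day 8-hour windows starting at hours 0-16 are formed; a
    window counts only if at least *min_hours_in_window* of its 8 hours are
    present, and a day with no valid window is missing.  Windows do not cross
    midnight.
    """
    if isinstance(hourly, pd.DataFrame) and {"date", "hour", "value"} <= set(hourly.columns):
        mat = _hourly_monitor_mean(hourly)
    elif isinstance(hourly, pd.Series):
        mat = hourly.unstack("hour").reindex(columns=range(24))
    else:
        mat = hourly.reindex(columns=range(24))
    vals = mat.to_numpy(dtype=float)
    win = np.lib.stride_tricks.sliding_window_view(vals, 8, axis=1)  # (days, 17, 8)
    n_ok = np.isfinite(win).sum(axis=2)
    wsum = np.nansum(win, axis=2)
    wmean = np.divide(wsum, n_ok, out=np.full(wsum.shape, np.nan), where=n_ok > 0)
    wmean[n_ok < min_hours_in_window] = np.nan
    with np.errstate(invalid="ignore"):
        out = np.nanmax(np.where(np.isfinite(wmean), wmean, -np.inf), axis=1)
    out[~np.isfinite(out)] = np.nan
    return pd.Series(out, index=mat.index, name="daily_max_8h")


def compute_aqhi(no2, o3, pm25, coef: AqhiCoefficients = AQHI_COEFFICIENTS):
    """Air Quality Health Index from daily NO2 (ppb), O3 (ppb) and PM2.5 (ug/m3).

    ``scale * (exp(c_no2*NO2) + exp(c_o3*O3) + exp(c_pm25*PM2.5) - 3)``;
    zero when all three inputs are zero, strictly increasing in each input,
    missing wherever any input is missing.
    """
    no2, o3, pm25 = (np.asarray(v, dtype=float) for v in (no2, o3, pm25))
    if np.nanmin(no2, initial=0) < 0 or np.nanmin(o3, initial=0) < 0 or np.nanmin(pm25, initial=0) < 0:
        raise ValueError("pollutant concentrations must be non-negative")
    out = coef.scale * (
        np.exp(coef.c_no2 * no2) + np.exp(coef.c_o3 * o3) + np.exp(coef.c_pm25 * pm25) - 3.0
    )
    if out.ndim == 0:
        return float(out)
    return out


def lag_series(series: pd.Series, k: int) -> pd.Series:
    """Value on day *d* becomes the input's value on day *d - k* (lag-k copy).

    The first *k* days of the (gap-free, daily) index are missing; lag 0 is
    the identity.
    """
    if k < 0:
        raise ValueError("lag must be non-negative")
    full = pd.date_range(series.index.min(), series.index.max(), freq="D")
    return series.reindex(full).shift(k)


def interquartile_range(
    series: pd.Series, pollutant: str = "", quantile_method: str = "linear"
) -> ScalingSpec:
    """Q3 - Q1 of the non-missing daily values, as an RR scaling constant.

    Quantiles use linear interpolation between order statistics (the common
    "type 7" convention) unless another numpy interpolation method is named.
    """
    vals = np.asarray(series, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least two non-missing values for an IQR")
    q1, q3 = np.percentile(vals, [25, 75], method=quantile_method)
    return ScalingSpec(pollutant=pollutant or getattr(series, "name", "") or "", iqr=float(q3 - q1),
                       quantile_method=quantile_method)


def build_daily_table(
    panels: dict[str, pd.DataFrame],
    temperature: pd.Series | None = None,
    completeness: float = 0.75,
    min_hours_in_window: int = 6,
) -> pd.DataFrame:
    """Assemble the daily analysis exposures from hourly pollutant panels.

    *panels* maps pollutant names (``no2``, ``o3``, ``pm25``) to hourly
    panels.  NO2 and PM2.5 become daily means, ozone the daily maximum 8-h
    mean; the AQHI is computed from the three daily metrics.  *temperature*
    is an already-daily series (degC) aligned by date.
    """
    cols = {}
    if "no2" in panels:
        cols["no2_ppb"] = daily_mean_across_monitors(panels["no2"], completeness)
    if "pm25" in panels:
        cols["pm25_ugm3"] = daily_mean_across_monitors(panels["pm25"], completeness)
    if "o3" in panels:
        cols["o3_ppb_max8h"] = daily_max_8h(panels["o3"], min_hours_in_window)
    daily = pd.DataFrame(cols)
    if temperature is not None:
        daily["temp_c"] = temperature
    if {"no2_ppb", "o3_ppb_max8h", "pm25_ugm3"} <= set(daily.columns):
        daily["aqhi"] = compute_aqhi(
            daily["no2_ppb"].to_numpy(),
            daily["o3_ppb_max8h"].to_numpy(),
            daily["pm25_ugm3"].to_numpy(),
        )
    return daily.rename_axis("date")
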