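"""Published aggregate reference data for the Toronto youth mental-health ED study.

These are small printed summary tables from the published Toronto analysis
(2004--2015): visit totals by sex, age group and disorder category, and the
marginal distribution of the daily environmental series.  They anchor the
aggregation checks and calibrate the synthetic-data generator; no record-level
data are included (the underlying NACRS records are confidential).
"""

from __future__ import annotations

import pandas as pd

#: Canonical disorder category labels, in reporting order.
CATEGORIES = (
    "organic",
    "substance_related",
    "schizophrenic_psychotic",
    "mood",
    "anxiety",
    "personality",
    "other",
)

AGE_GROUPS = ("8-12", "13-18", "19-24")

# Published ED-visit totals per (sex, age group, category), Toronto 2004-2015.
_VISIT_TOTALS = {
    ("M", "8-12"): (82, 11, 81, 185, 435, 23, 1110),
    ("M", "13-18"): (186, 3662, 1540, 2514, 1774, 178, 2051),
    ("M", "19-24"): (219, 8405, 7107, 4718, 4777, 444, 1674),
    ("F", "8-12"): (44, 11, 93, 242, 492, 9, 526),
    ("F", "13-18"): (181, 3460, 1169, 4835, 3104, 438, 2722),
    ("F", "19-24"): (229, 6019, 3486, 6597, 6009, 1067, 2076),
}


def toronto_visit_totals() -> pd.DataFrame:
    """Study-period ED-visit totals in tidy form.

    Returns a DataFrame with columns ``sex, age_group, category, count``:
    one row per (sex, age-group, disorder-category) cell of the published
    summary table (42 cells, grand total 83,985 visits).
    """
    rows = [
        {"sex": sex, "age_group": age, "category": cat, "count": n}
        for (sex, age), counts in _VISIT_TOTALS.items()
        for cat, n in zip(CATEGORIES, counts)
    ]
    return pd.DataFrame(rows)


def toronto_environment_summary() -> pd.DataFrame:
    """Marginal summary of the daily environmental series and total ED visits.

    Rows: minimum, q1, median, mean, q3, maximum.  Columns: temperature (degC),
    daily-maximum 8-h ozone (ppb), NO2 (ppb), PM2.5 (ug/m3), AQHI, and the
    all-cause daily ED-visit count.  Used as calibration anchors for the
    synthetic-data generator and for IQR arithmetic.
    """
    data = {
        "temp_c": [-22.2, 1.7, 10.0, 9.5, 18.4, 31.2],
        "o3_ppb": [3.3, 24.0, 31.5, 33.1, 40.0, 85.9],
        "no2_ppb": [4.0, 12.0, 16.1, 17.3, 21.2, 62.3],
        "pm25_ugm3": [0.1, 3.8, 6.0, 7.7, 9.8, 44.8],
        "aqhi": [1.0, 2.4, 2.8, 2.9, 3.3, 7.1],
        "ed_visits": [2, 15, 19, 20, 23, 60],
    }
    return pd.DataFrame(data, index=["minimum", "q1", "median", "mean", "q3", "maximum"])


def subgroup_shares() -> pd.DataFrame:
    """Fraction of all visits in each (sex, age_group, category) cell.

    Derived from :func:`toronto_visit_totals`; used as the default multinomial
    split of the simulated daily totals.
    """
    tot = toronto_visit_totals()
    tot = tot.assign(share=tot["count"] / tot["count"].sum())
    return tot.drop(columns="count")
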