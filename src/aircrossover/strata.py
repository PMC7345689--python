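"""Time-stratified case-crossover structure.

Every study day is assigned to the stratum of days sharing its year, month
and day of week; within a month each such stratum holds 4 or 5 days
depending on month length.  Conditioning on these strata mimics the
time-stratified referent selection of the classical case-crossover design
(each case day's referents are the other same-weekday days of its month),
which avoids overlap bias and removes long-term trend, seasonality and
day-of-week structure by design.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

__all__ = ["StratumIndex", "build_strata", "stratum_labels", "referent_set"]

_WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def stratum_labels(dates: pd.DatetimeIndex | Sequence) -> pd.Series:
    """Stratum label ``YYYY-MM:kDow`` for each date (ISO weekday number, Mon=1)."""
    idx = pd.DatetimeIndex(dates)
    dow = idx.dayofweek  # Monday = 0
    labels = (
        idx.strftime("%Y-%m")
        + ":"
        + pd.Index([f"{d + 1}{_WEEKDAYS[d]}" for d in dow])
    )
    return pd.Series(labels, index=idx, name="stratum")


class StratumIndex:
    """Bidirectional map between calendar days and their (year, month, weekday) strata."""

    def __init__(self, dates: Iterable):
        idx = pd.DatetimeIndex(dates)
        if idx.has_duplicates:
            raise ValueError("dates must be unique")
        self._labels = stratum_labels(idx.sort_values())
        self._members: dict[str, pd.DatetimeIndex] = {
            key: grp.index for key, grp in self._labels.groupby(self._labels)
        }

    @property
    def labels(self) -> pd.Series:
        """Series mapping each date to its stratum label."""
        return self._labels

    @property
    def strata(self) -> dict[str, pd.DatetimeIndex]:
        return self._members

    def __len__(self) -> int:
        return len(self._members)

    def sizes(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self._members.items()}, name="size")

    def stratum_of(self, date) -> str:
        date = pd.Timestamp(date)
        try:
            return self._labels.loc[date]
        except KeyError:
            raise KeyError(f"{date.date()} is not an indexed study day") from None

    def members(self, key: str) -> pd.DatetimeIndex:
        return self._members[key]

    def referent_set(self, date) -> pd.DatetimeIndex:
        """All other days of *date*'s stratum (its case-crossover referents).

        A singleton stratum yields an empty set: such a day is
        non-informative for the conditional analysis.
        """
        date = pd.Timestamp(date)
        members = self._members[self.stratum_of(date)]
        return members[members != date]


def build_strata(dates: Iterable) -> StratumIndex:
    """Partition study days into (year, month, day-of-week) strata."""
    return StratumIndex(dates)


def referent_set(date, index: StratumIndex) -> pd.DatetimeIndex:
    """Functional form of :meth:`StratumIndex.referent_set`."""
    return index.referent_set(date)
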