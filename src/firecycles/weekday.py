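"""Weekday partition of the mean-function posterior and weekday-comparison tables.

The posterior of the mean function on a window of whole weeks is split
into the seven interleaved weekday sub-series t_i = i, i+7, ... with
1 = Monday and 7 = Sunday.  The membership table gives, per weekday, the
posterior probability that its mean-function sub-vector lies entirely
inside the simultaneous band segment derived for Sunday; the exceedance
table gives the probability that it lies entirely above Sunday's estimated
(posterior-mean) function.  Small membership and large exceedance
probabilities for the other weekdays are evidence of a Sunday minimum.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .bands import CredibleBand, ProbabilityEstimate, exceedance_probability, interval_probability
from .ingest import ANTHROME_GROUPS, WEEKDAY_NAMES, FireRecordSet
from .model import MeanFunctionPosterior

__all__ = [
    "CyclePeriodReport",
    "WeekdayPartition",
    "WeekdayTable",
    "anthrome_share_table",
    "exceedance_table",
    "membership_table",
    "partition_by_weekday",
    "strongest_cycle_window",
]

SUNDAY = 7


@dataclass(frozen=True)
class WeekdayPartition:
    """Per-weekday sub-vectors of a mean-function posterior and its band.

    ``indices[i]`` are 0-based positions of weekday i (1=Monday..7=Sunday)
    within the window; sub-means, sub-covariances, cross-covariances with
    Sunday and the band segments are extracted by index arithmetic.
    """

    mfp: MeanFunctionPosterior
    band: CredibleBand
    start_weekday: int
    indices: Mapping[int, np.ndarray]

    @property
    def n_weeks(self) -> int:
        return len(self.mfp) // 7

    def mean(self, i: int) -> np.ndarray:
        return self.mfp.mean[self.indices[i]]

    def cov(self, i: int, j: int | None = None) -> np.ndarray:
        j = i if j is None else j
        return self.mfp.cov[np.ix_(self.indices[i], self.indices[j])]

    def cross_sunday(self, i: int) -> np.ndarray:
        return self.cov(i, SUNDAY)

    def lower(self, i: int) -> np.ndarray:
        return self.band.lower[self.indices[i]]

    def upper(self, i: int) -> np.ndarray:
        return self.band.upper[self.indices[i]]

    def week_dates(self) -> pd.DatetimeIndex | None:
        dates = self.mfp.dates()
        return None if dates is None else dates[self.indices[self.start_weekday]]


@dataclass(frozen=True)
class WeekdayTable:
    """Seven weekday probability estimates against a reference day."""

    table: pd.DataFrame
    kind: str  # "membership" or "exceedance"
    reference_day: int = SUNDAY


@dataclass(frozen=True)
class CyclePeriodReport:
    """Longest run of weeks in which the weekly cycle is active.

    ``weekday_exceed_counts[w]`` counts the non-Sunday weekdays whose
    estimated mean exceeds Sunday's upper band in week w; the run is the
    longest stretch of consecutive weeks with at least ``threshold_days``
    such weekdays (ties resolved to the earliest run)."""

    weekday_exceed_counts: np.ndarray
    run_start_week: int | None
    run_end_week: int | None
    threshold_days: int
    run_start_date: dt.date | None = None
    run_end_date: dt.date | None = None

    @property
    def run_length(self) -> int:
        if self.run_start_week is None:
            return 0
        return self.run_end_week - self.run_start_week + 1


def partition_by_weekday(
    mfp: MeanFunctionPosterior, band: CredibleBand, start_weekday: int = 1
) -> WeekdayPartition:
    """Split a whole-week window into the seven weekday sub-series."""
    n = len(mfp)
    if n % 7:
        raise ValueError("window length must be divisible by 7")
    if len(band.lower) != n:
        raise ValueError("band was not built on the same window as the posterior")
    if not 1 <= start_weekday <= 7:
        raise ValueError("start_weekday must be in 1..7")
    pos = np.arange(n)
    weekday = (start_weekday - 1 + pos) % 7 + 1
    indices = {i: pos[weekday == i] for i in range(1, 8)}
    return WeekdayPartition(mfp=mfp, band=band, start_weekday=start_weekday, indices=indices)


def membership_table(
    partition: WeekdayPartition, n_mc: int = 100_000, seed: int | None = None
) -> WeekdayTable:
    """P(LB_sunday <= M_{t_i} <= UB_sunday week-by-week), for each weekday i."""
    lb = partition.lower(SUNDAY)
    ub = partition.upper(SUNDAY)
    rows = {}
    for i in range(1, 8):
        est = interval_probability(
            partition.mean(i),
            partition.cov(i),
            lb,
            ub,
            n_mc=n_mc,
            seed=None if seed is None else seed + i,
        )
        rows[WEEKDAY_NAMES[i - 1]] = (est.estimate, est.se)
    df = pd.DataFrame(rows, index=["estimate", "mc_error"]).T
    return WeekdayTable(table=df, kind="membership")


def exceedance_table(
    partition: WeekdayPartition, n_mc: int = 100_000, seed: int | None = None
) -> WeekdayTable:
    """P(M_{t_i} > M̂_sunday for every week), against Sunday's posterior means."""
    threshold = partition.mean(SUNDAY)
    rows = {}
    for i in range(1, 8):
        est = exceedance_probability(
            partition.mean(i),
            partition.cov(i),
            threshold,
            n_mc=n_mc,
            seed=None if seed is None else seed + 10 * i,
        )
        rows[WEEKDAY_NAMES[i - 1]] = (est.estimate, est.se)
    df = pd.DataFrame(rows, index=["estimate", "mc_error"]).T
    return WeekdayTable(table=df, kind="exceedance")


def strongest_cycle_window(
    partition: WeekdayPartition, threshold_days: int = 1
) -> CyclePeriodReport:
    """Locate the longest run of weeks in which at least ``threshold_days``
    non-Sunday weekdays have an estimated mean above Sunday's upper band."""
    ub_sunday = partition.upper(SUNDAY)
    counts = np.zeros(partition.n_weeks, dtype=int)
    for i in range(1, 7):
        counts += partition.mean(i) > ub_sunday
    active = counts >= threshold_days

    best_start = best_len = 0
    cur_start = cur_len = 0
    for w, a in enumerate(active):
        if a:
            if cur_len == 0:
                cur_start = w
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0

    if best_len == 0:
        return CyclePeriodReport(counts, None, None, threshold_days)
    start_w, end_w = best_start, best_start + best_len - 1
    dates = partition.mfp.dates()
    d0 = d1 = None
    if dates is not None:
        d0 = dates[start_w * 7].date()
        d1 = dates[end_w * 7 + 6].date()
    return CyclePeriodReport(counts, start_w, end_w, threshold_days, d0, d1)


def anthrome_share_table(data: FireRecordSet | Mapping[str, int]) -> pd.DataFrame:
    """Fire counts and percent shares per anthrome group.

    Accepts a labeled record set or a mapping group -> count; percents are
    over the six groups (unlabeled records excluded), rounded to 2 decimals."""
    if isinstance(data, FireRecordSet):
        counts = data.records["anthrome_group"].value_counts()
        mapping = {g: int(counts.get(g, 0)) for g in ANTHROME_GROUPS}
    else:
        mapping = {g: int(data.get(g, 0)) for g in ANTHROME_GROUPS}
    total = sum(mapping.values())
    if total == 0:
        raise ValueError("no labeled records to tabulate")
    return pd.DataFrame(
        {
            "group": list(ANTHROME_GROUPS),
            "fires": [mapping[g] for g in ANTHROME_GROUPS],
            "percent": [round(100.0 * mapping[g] / total, 2) for g in ANTHROME_GROUPS],
        }
    )
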