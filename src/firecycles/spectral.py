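"""Spectral detection of hidden periodicities in daily count series.

Implements the periodogram at Fourier frequencies, Fisher's exact g-test
for the largest ordinate under a Gaussian white-noise null, Whittle's
sequential extension to lower-ranked ordinates, harmonic de-seasonalization
by least squares, and an iterative cycle-detection procedure that alternates
testing and de-seasonalization.  The nominal frequency set for daily fire
counts is one cycle per 365 days with its first three harmonics plus the
7-day and 3.5-day cycles.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .ingest import DailyCountSeries

__all__ = [
    "FrequencySet",
    "LogCountSeries",
    "PeriodicityTest",
    "PeriodogramResult",
    "NOMINAL_FREQUENCIES",
    "detect_cycles",
    "fisher_g_pvalue",
    "fisher_gtest",
    "harmonic_deseasonalize",
    "log_transform",
    "periodogram",
    "sample_acf_pacf",
    "whittle_sequential_test",
]

ANNUAL = 2 * np.pi / 365
WEEKLY = 2 * np.pi / 7

#: Nominal angular frequencies (rad/day): annual + 3 harmonics, 7-day, 3.5-day.
NOMINAL_FREQUENCIES = (ANNUAL, 2 * ANNUAL, 3 * ANNUAL, 4 * ANNUAL, WEEKLY, 2 * WEEKLY)


@dataclass(frozen=True)
class LogCountSeries:
    """A log-transformed daily count series, t = 1..n."""

    values: np.ndarray
    start_date: dt.date
    label: str = "global"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("values must be a finite 1-d array")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FrequencySet:
    """An ordered set of distinct angular frequencies in (0, pi)."""

    omegas: tuple[float, ...]

    def __post_init__(self) -> None:
        om = tuple(float(w) for w in self.omegas)
        if len(set(om)) != len(om):
            raise ValueError("frequencies must be distinct")
        if any(not (0 < w < np.pi) for w in om):
            raise ValueError("all angular frequencies must lie in (0, pi)")
        object.__setattr__(self, "omegas", om)

    @classmethod
    def default(cls) -> "FrequencySet":
        return cls(NOMINAL_FREQUENCIES)

    def __iter__(self):
        return iter(self.omegas)

    def __len__(self) -> int:
        return len(self.omegas)

    def periods_days(self) -> tuple[float, ...]:
        return tuple(2 * np.pi / w for w in self.omegas)


@dataclass(frozen=True)
class PeriodogramResult:
    """Periodogram ordinates I(omega_j) at Fourier frequencies j = 1..⌊(n−1)/2⌋."""

    n: int
    ordinates: np.ndarray
    omegas: np.ndarray
    nyquist_ordinate: float | None = None
    total_ss: float = 0.0  # sum of squared deviations of the input

    @property
    def j(self) -> np.ndarray:
        return np.arange(1, len(self.ordinates) + 1)

    def parseval_gap(self) -> float:
        """Relative gap of the Parseval identity (0 for an exact transform)."""
        total = 2 * float(np.sum(self.ordinates))
        if self.nyquist_ordinate is not None:
            total += self.nyquist_ordinate
        denom = self.total_ss if self.total_ss > 0 else 1.0
        return abs(total - self.total_ss) / denom

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "j": self.j,
                "omega": self.omegas,
                "period_days": 2 * np.pi / self.omegas,
                "ordinate": self.ordinates,
            }
        )


@dataclass(frozen=True)
class PeriodicityTest:
    """One Fisher/Whittle test of a ranked periodogram ordinate."""

    frequency: float
    rank: int
    g: float
    m: int
    p_value: float

    @property
    def period_days(self) -> float:
        return 2 * np.pi / self.frequency


def log_transform(series: DailyCountSeries, offset: int = 0) -> LogCountSeries:
    """y_t = ln(count_t + offset); zero counts require offset 1."""
    if offset not in (0, 1):
        raise ValueError("offset must be 0 or 1")
    counts = series.counts
    if np.any(counts + offset <= 0):
        raise ValueError(
            "series contains zero counts; call log_transform(series, offset=1)"
        )
    return LogCountSeries(
        values=np.log(counts + float(offset)), start_date=series.start_date, label=series.label
    )


def periodogram(series: LogCountSeries) -> PeriodogramResult:
    """I(omega_j) = |sum_t (y_t - ybar) e^{-i t omega_j}|^2 / n at Fourier frequencies."""
    y = series.values
    n = len(y)
    if n < 3:
        raise ValueError("periodogram requires n >= 3")
    yc = y - y.mean()
    spec = np.abs(np.fft.rfft(yc)) ** 2 / n
    m = (n - 1) // 2
    ordinates = spec[1 : m + 1]
    omegas = 2 * np.pi * np.arange(1, m + 1) / n
    nyq = float(spec[n // 2]) if n % 2 == 0 else None
    return PeriodogramResult(
        n=n,
        ordinates=ordinates,
        omegas=omegas,
        nyquist_ordinate=nyq,
        total_ss=float(np.sum(yc**2)),
    )


def fisher_g_pvalue(g: float, m: int) -> float:
    """Exact null p-value of Fisher's g statistic for m periodogram ordinates.

    p = sum_{j=1}^{⌊1/g⌋} (-1)^{j-1} C(m, j) (1 - j g)^{m-1}, clipped to [0, 1].
    Terms are evaluated in log-gamma space.  Deep in the non-significant
    regime (g near its minimum 1/m) the alternating series is numerically
    unstable but the p-value is 1 to working precision, which is returned.
    """
    if not (0 < g <= 1):
        raise ValueError("g must lie in (0, 1]")
    if m < 2:
        raise ValueError("m must be >= 2")
    if g == 1.0:
        return 0.0
    jmax = min(m, int(math.floor(1.0 / g)))
    terms = []
    max_log = -np.inf
    for j in range(1, jmax + 1):
        one_minus = 1.0 - j * g
        if one_minus <= 0.0:
            break
        log_t = (
            gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1) + (m - 1) * math.log(one_minus)
        )
        max_log = max(max_log, log_t)
        if log_t < max_log - 60 and j > 2:
            break  # remaining terms are negligible
        terms.append((1 if j % 2 else -1) * math.exp(min(log_t, 700.0)))
    if max_log > 25:
        # alternating series unstable; occurs only when p is 1 to working precision
        return 1.0
    p = math.fsum(terms)
    return float(min(max(p, 0.0), 1.0))


def _ranked(pgram: PeriodogramResult) -> np.ndarray:
    # descending ordinate; ties (to 1 part in 1e9) broken toward the lower frequency
    scale = pgram.ordinates.max(initial=0.0)
    key = np.round(pgram.ordinates / scale, 9) if scale > 0 else pgram.ordinates
    return np.lexsort((pgram.omegas, -key))


def fisher_gtest(pgram: PeriodogramResult, exclude_ranks: int = 0) -> PeriodicityTest:
    """Fisher's g-test of the largest ordinate after removing the ``exclude_ranks`` larger ones."""
    order = _ranked(pgram)
    remaining = order[exclude_ranks:]
    m = len(remaining)
    if m < 2:
        raise ValueError("fewer than 2 ordinates remain after exclusion")
    vals = pgram.ordinates[remaining]
    top = remaining[0]
    total = float(vals.sum())
    if total <= 0:
        # flat spectrum: no periodicity, g at its degenerate minimum
        return PeriodicityTest(
            frequency=float(pgram.omegas[top]), rank=exclude_ranks + 1, g=1.0 / m, m=m, p_value=1.0
        )
    g = float(vals[0] / total)
    return PeriodicityTest(
        frequency=float(pgram.omegas[top]),
        rank=exclude_ranks + 1,
        g=g,
        m=m,
        p_value=fisher_g_pvalue(g, m),
    )


def whittle_sequential_test(
    pgram: PeriodogramResult, max_peaks: int = 10, alpha: float = 0.05
) -> list[PeriodicityTest]:
    """Whittle's sequential test: Fisher's test applied to the r-th largest ordinate
    after removing the r−1 larger ones, stopping at the first non-significant rank
    (which is included in the returned list) or at ``max_peaks``."""
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    tests: list[PeriodicityTest] = []
    for r in range(max_peaks):
        if len(pgram.ordinates) - r < 2:
            break
        t = fisher_gtest(pgram, exclude_ranks=r)
        tests.append(t)
        if t.p_value > alpha:
            break
    return tests


def _harmonic_design(n: int, freqs: Sequence[float]) -> np.ndarray:
    t = np.arange(1, n + 1, dtype=float)
    cols = [np.ones(n), t]
    for w in freqs:
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


def harmonic_deseasonalize(
    series: LogCountSeries, freqs: FrequencySet
) -> tuple[np.ndarray, LogCountSeries]:
    """OLS fit of y on {1, t, cos(w_i t), sin(w_i t)}; returns (coefficients, residual series)."""
    n = len(series)
    k = len(freqs)
    if n <= 2 * k + 2:
        raise ValueError("series too short for the requested number of harmonics")
    X = _harmonic_design(n, list(freqs))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear harmonic design (duplicated or aliased frequency)")
    coef, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    resid = series.values - X @ coef
    return coef, LogCountSeries(values=resid, start_date=series.start_date, label=series.label)


def _snap_to_nominal(omega: float, n: int) -> float:
    """Snap a Fourier frequency to the nearest nominal frequency within one bin."""
    bin_width = 2 * np.pi / n
    for nominal in NOMINAL_FREQUENCIES:
        if abs(omega - nominal) <= bin_width:
            return nominal
    return omega


def detect_cycles(
    series: LogCountSeries,
    alpha: float = 0.01,
    candidate_rounds: int = 2,
    max_peaks: int = 30,
    snap: bool = True,
) -> FrequencySet:
    """Iteratively detect significant periodicities.

    Each round computes the periodogram of the current residual series, runs
    the sequential Whittle test at level ``alpha``, collects the significant
    Fourier frequencies (snapped to the nearest nominal frequency when within
    one Fourier bin), de-seasonalizes the original series at everything
    collected so far, and repeats.  Frequencies within one Fourier bin of an
    earlier detection are not collected again.
    """
    n = len(series)
    bin_width = 2 * np.pi / n
    detected: list[float] = []
    work = series
    for _ in range(candidate_rounds):
        pg = periodogram(work)
        tests = whittle_sequential_test(pg, max_peaks=max_peaks, alpha=alpha)
        new = []
        for t in tests:
            if t.p_value > alpha:
                continue
            w = _snap_to_nominal(t.frequency, n) if snap else t.frequency
            if all(abs(w - d) > bin_width for d in detected + new):
                new.append(w)
        if not new:
            break
        detected.extend(new)
        _, work = harmonic_deseasonalize(series, FrequencySet(tuple(sorted(detected))))
    return FrequencySet(tuple(sorted(detected)))


def sample_acf_pacf(
    series: LogCountSeries, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ACF (biased denominator) and PACF (Durbin–Levinson), lags 0..max_lag."""
    n = len(series)
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < n/2")
    a = _sm_acf(series.values, nlags=max_lag, fft=True, adjusted=False)
    p = _sm_pacf(series.values, nlags=max_lag, method="ldb")
    return np.asarray(a), np.asarray(p)


def tests_to_frame(tests: Sequence[PeriodicityTest]) -> pd.DataFrame:
    """Tabular export of a sequence of periodicity tests."""
    return pd.DataFrame(
        {
            "rank": [t.rank for t in tests],
            "period_days": [t.period_days for t in tests],
            "g": [t.g for t in tests],
            "m": [t.m for t in tests],
            "p": [t.p_value for t in tests],
        }
    )
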