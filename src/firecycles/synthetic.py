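"""Synthetic daily fire-count series and fire-record sets.

The generator realizes the working model for daily vegetation-fire counts:
the log of the daily count follows a linear trend plus a six-harmonic mean
function (annual cycle with three harmonics, plus 7-day and 3.5-day
cycles), optional additive weekday offsets, and stationary zero-mean AR(7)
Gaussian noise.  Counts are either the rounded exponential of the log
series ("round-lognormal") or Poisson draws around it.  Fire-record point
sets place the daily counts uniformly inside the cells of an anthrome
class raster, one intensity series per anthrome group.

:func:`global_fire_preset` ships coefficients that mirror the published
posterior means of the fitted global model, so that default simulations
resemble the real global fire-count series.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .ingest import (
    ANTHROME_CODE_TO_GROUP,
    AnthromeGrid,
    DailyCountSeries,
    FireRecordSet,
    VALID_ANTHROME_CODES,
)
from .spectral import ANNUAL, WEEKLY, LogCountSeries

__all__ = [
    "SimulationSpec",
    "global_fire_preset",
    "make_toy_anthrome_grid",
    "simulate_count_series",
    "simulate_fire_records",
    "simulate_log_series",
    "true_mean_vector",
]

#: Burn-in samples discarded before the AR draw is used.
AR_BURN_IN = 500


def _ar_is_stationary(coefficients: tuple[float, ...]) -> bool:
    phi = np.asarray(coefficients, dtype=float)
    if phi.size == 0 or not phi.any():
        return True
    roots = np.roots(np.r_[1.0, -phi])
    return bool(np.all(np.abs(roots) < 1.0))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic daily-count series.

    ``harmonic_terms`` are (angular frequency rad/day, cosine coefficient,
    sine coefficient) triples; ``weekday_offsets`` are additive log-scale
    offsets indexed Monday..Sunday; ``ar_coefficients`` define the noise
    AR polynomial, which must be stationary.
    """

    intercept: float = 0.0
    trend: float = 0.0
    harmonic_terms: tuple[tuple[float, float, float], ...] = ()
    weekday_offsets: tuple[float, ...] = (0.0,) * 7
    ar_coefficients: tuple[float, ...] = ()
    innovation_sd: float = 0.1
    n_days: int = 3675
    start_date: dt.date = dt.date(2002, 7, 8)
    count_mode: str = "round-lognormal"
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")
        if len(self.weekday_offsets) != 7:
            raise ValueError("weekday_offsets must have 7 entries (Monday..Sunday)")
        if len(self.ar_coefficients) > 7:
            raise ValueError("at most 7 AR coefficients are supported")
        if not _ar_is_stationary(tuple(self.ar_coefficients)):
            raise ValueError(
                "AR coefficients are non-stationary: the polynomial 1 - sum(phi_i z^i) "
                "must have all roots outside the unit circle"
            )
        for w, _, _ in self.harmonic_terms:
            if not (0 < w < np.pi):
                raise ValueError(f"angular frequency {w} outside (0, pi)")
        if self.count_mode not in ("round-lognormal", "poisson"):
            raise ValueError("count_mode must be 'round-lognormal' or 'poisson'")


def global_fire_preset(
    seed: int = 0,
    weekday_offsets: tuple[float, ...] = (0.0,) * 7,
    n_days: int = 3675,
    count_mode: str = "round-lognormal",
) -> SimulationSpec:
    """Preset mirroring the published posterior means of the fitted global model.

    The harmonic coefficients and intercept/trend are the published
    posterior means (annual cycle and its first three harmonics plus the
    7-day and 3.5-day cycles).  The AR(7) coefficients and innovation sd
    were never published; the values here are this package's own choice of
    a realistic noise process for global daily log fire counts — moderate
    synoptic-scale persistence (lag-1 autocorrelation about 0.6), a mild
    residual weekly (lag-7) component, and a marginal residual spread of
    roughly 0.15 on the log scale.
    """
    return SimulationSpec(
        intercept=9.3405,
        trend=-2.3729e-05,
        harmonic_terms=(
            (ANNUAL, 0.18654, 0.26376),
            (2 * ANNUAL, 0.17998, 0.11867),
            (3 * ANNUAL, -0.047871, 0.13137),
            (4 * ANNUAL, -0.0067088, -0.086432),
            (WEEKLY, -0.042395, 0.010734),
            (2 * WEEKLY, -0.033660, -0.010493),
        ),
        weekday_offsets=tuple(weekday_offsets),
        ar_coefficients=(0.55, 0.08, 0.04, 0.02, 0.01, 0.005, 0.05),
        innovation_sd=0.10,
        n_days=n_days,
        count_mode=count_mode,
        seed=seed,
        label="global-preset",
    )


def true_mean_vector(spec: SimulationSpec) -> np.ndarray:
    """Noiseless mean of the log series (trend + harmonics + weekday offsets), t = 1..n."""
    t = np.arange(1, spec.n_days + 1, dtype=float)
    mean = spec.intercept + spec.trend * t
    for w, c, d in spec.harmonic_terms:
        mean += c * np.cos(w * t) + d * np.sin(w * t)
    start_wd = spec.start_date.weekday()  # 0 = Monday
    weekday_idx = (start_wd + np.arange(spec.n_days)) % 7
    mean += np.asarray(spec.weekday_offsets, dtype=float)[weekday_idx]
    return mean


def _simulate_ar(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    phi = np.asarray(spec.ar_coefficients, dtype=float)
    burn = AR_BURN_IN + len(phi)
    z = rng.normal(0.0, spec.innovation_sd, size=spec.n_days + burn)
    if phi.size and phi.any():
        x = lfilter([1.0], np.r_[1.0, -phi], z)
    else:
        x = z
    return x[burn:]


def simulate_log_series(spec: SimulationSpec) -> tuple[LogCountSeries, np.ndarray]:
    """Draw y_t = mean_t + X_t with X_t stationary AR noise; returns (series, true mean)."""
    rng = np.random.default_rng(spec.seed)
    mean = true_mean_vector(spec)
    x = _simulate_ar(spec, rng)
    series = LogCountSeries(values=mean + x, start_date=spec.start_date, label=spec.label)
    return series, mean


def _counts_from_log(
    y: np.ndarray, mode: str, rng: np.random.Generator
) -> np.ndarray:
    over = np.flatnonzero(y > 700.0)  # exp overflow guard
    if over.size:
        t_bad = int(over[0]) + 1
        raise OverflowError(f"exp(y_t) overflows at t={t_bad} (y={y[over[0]]:.3g})")
    lam = np.exp(y)
    if mode == "round-lognormal":
        return np.rint(lam).astype(np.int64)
    return rng.poisson(lam).astype(np.int64)


def simulate_count_series(spec: SimulationSpec) -> DailyCountSeries:
    """Count-scale realization: rint(exp(y_t)) or Poisson(exp(y_t)) per ``count_mode``."""
    series, _ = simulate_log_series(spec)
    rng = np.random.default_rng((spec.seed, 0xC0117))
    counts = _counts_from_log(series.values, spec.count_mode, rng)
    return DailyCountSeries(start_date=spec.start_date, counts=counts, label=spec.label)


def make_toy_anthrome_grid(
    nrows: int,
    ncols: int,
    class_layout: Mapping[tuple[int, int, int, int], int],
    cellsize: float = 1.0 / 12.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: int = -9999,
) -> AnthromeGrid:
    """Build a toy anthrome raster from rectangular blocks.

    ``class_layout`` maps half-open blocks ``(row_start, row_stop,
    col_start, col_stop)`` to anthrome class codes (or the nodata value).
    The blocks must tile the grid exactly: overlaps and gaps are rejected.
    """
    cover = np.zeros((nrows, ncols), dtype=int)
    codes = np.full((nrows, ncols), nodata, dtype=int)
    for (r0, r1, c0, c1), code in class_layout.items():
        if not (0 <= r0 < r1 <= nrows and 0 <= c0 < c1 <= ncols):
            raise ValueError(f"block {(r0, r1, c0, c1)} falls outside the {nrows}x{ncols} grid")
        if code != nodata and code not in VALID_ANTHROME_CODES:
            raise ValueError(f"invalid anthrome code {code}")
        if cover[r0:r1, c0:c1].any():
            raise ValueError(f"block {(r0, r1, c0, c1)} overlaps an earlier block")
        cover[r0:r1, c0:c1] = 1
        codes[r0:r1, c0:c1] = code
    if not cover.all():
        raise ValueError("blocks do not tile the grid: uncovered cells remain")
    return AnthromeGrid(
        ncols=ncols,
        nrows=nrows,
        xllcorner=xllcorner,
        yllcorner=yllcorner,
        cellsize=cellsize,
        nodata=nodata,
        codes=codes,
    )


def simulate_fire_records(
    per_class_specs: Mapping[str, SimulationSpec],
    grid: AnthromeGrid,
    seed: int = 0,
    code_to_group: Mapping[int, str] | None = None,
) -> FireRecordSet:
    """Realize fire records: per anthrome group, daily counts from the group's
    simulation spec placed uniformly at random inside the group's grid cells.

    Satellites alternate T/A per record (cosmetic, with morning/afternoon
    overpass times); confidence is 100 and type 0 so default screening is
    a no-op.  The daily record totals per group equal the group's simulated
    count series exactly.
    """
    mapping = dict(ANTHROME_CODE_TO_GROUP if code_to_group is None else code_to_group)
    group_cells: dict[str, np.ndarray] = {}
    for group in per_class_specs:
        codes = [c for c, g in mapping.items() if g == group]
        cells = np.argwhere(np.isin(grid.codes, codes))
        if len(cells) == 0:
            raise ValueError(f"anthrome group {group!r} occupies no cells in the grid")
        group_cells[group] = cells

    dates, times, sats, lats, lons = [], [], [], [], []
    for gi, (group, spec) in enumerate(sorted(per_class_specs.items())):
        counts = simulate_count_series(spec)
        rng = np.random.default_rng((seed, gi, 0xF17E))
        cells = group_cells[group]
        total = int(counts.counts.sum())
        cell_idx = rng.integers(0, len(cells), size=total)
        u = rng.random(total)
        v = rng.random(total)
        rows = cells[cell_idx, 0]
        cols = cells[cell_idx, 1]
        lat = grid.ytopcorner - (rows + u) * grid.cellsize
        lon = grid.xllcorner + (cols + v) * grid.cellsize
        day_of_record = np.repeat(np.arange(len(counts)), counts.counts)
        rec_dates = pd.Timestamp(counts.start_date) + pd.to_timedelta(day_of_record, unit="D")
        sat = np.where(np.arange(total) % 2 == 0, "T", "A")
        minutes = np.where(sat == "T", 10 * 60 + 30, 13 * 60 + 30)
        dates.append(rec_dates)
        times.append(minutes)
        sats.append(sat)
        lats.append(lat)
        lons.append(lon)

    if dates:
        all_dates = pd.DatetimeIndex(np.concatenate([d.values for d in dates]))
        all_times = np.concatenate(times)
        all_sats = np.concatenate(sats)
        all_lats = np.concatenate(lats)
        all_lons = np.concatenate(lons)
        order = np.argsort(all_dates.values, kind="stable")
    else:  # pragma: no cover - empty mapping
        all_dates = pd.DatetimeIndex([])
        all_times = all_sats = all_lats = all_lons = np.array([])
        order = np.array([], dtype=int)

    n = len(order)
    return FireRecordSet.from_columns(
        acq_date=all_dates[order],
        acq_time=all_times[order].astype(np.int64),
        satellite=pd.array(all_sats[order], dtype="string"),
        lat=all_lats[order],
        lon=all_lons[order],
        confidence=np.full(n, 100, dtype=np.int64),
        type_code=np.zeros(n, dtype=np.int64),
    )
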