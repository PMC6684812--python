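"""Reading, screening, anthrome-labelling and daily aggregation of active-fire records.

The record dialect is the MODIS MCD14ML fire-location text format: one
detection per line with acquisition date/time, satellite, coordinates,
brightness/FRP fields (ignored here), detection confidence and a type code
(0 = presumed vegetation fire).  Anthrome class rasters are ESRI ASCII
grids; each detection is labelled with the class of the cell containing it
and classes are collapsed into the six aggregate anthrome groups.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ANTHROME_CODE_TO_GROUP",
    "ANTHROME_GROUPS",
    "AnthromeGrid",
    "DailyCountSeries",
    "FireRecordSet",
    "aggregate_daily",
    "assign_anthromes",
    "count_full_weeks",
    "grid_summary",
    "read_anthrome_grid",
    "read_count_series_csv",
    "read_mcd14ml",
    "screen_records",
    "trim_to_full_weeks",
    "weekday_summary",
    "write_anthrome_grid",
    "write_count_series_csv",
    "write_mcd14ml",
]

#: Aggregate anthrome groups, in conventional intensity order.
ANTHROME_GROUPS = (
    "Settlements",
    "Villages",
    "Croplands",
    "Rangelands",
    "Seminatural",
    "Wildlands",
)

#: Default Anthromes-v2 class-code to aggregate-group mapping.
ANTHROME_CODE_TO_GROUP: dict[int, str] = {
    **{c: "Settlements" for c in (11, 12)},
    **{c: "Villages" for c in (21, 22, 23, 24)},
    **{c: "Croplands" for c in (31, 32, 33, 34)},
    **{c: "Rangelands" for c in (41, 42, 43)},
    **{c: "Seminatural" for c in (51, 52, 53, 54)},
    **{c: "Wildlands" for c in (61, 62, 63)},
}

#: Valid anthrome class codes.
VALID_ANTHROME_CODES = frozenset(ANTHROME_CODE_TO_GROUP)

#: Columns of the in-memory record table.
RECORD_COLUMNS = (
    "acq_date",
    "acq_time",
    "satellite",
    "lat",
    "lon",
    "confidence",
    "type_code",
    "anthrome_code",
    "anthrome_group",
)

_REQUIRED_FILE_COLUMNS = ("YYYYMMDD", "HHMM", "sat", "lat", "lon", "conf", "type")

# Column order of the full 11-column MCD14ML line and of the 7-column
# reduced dialect (brightness/FRP fields omitted).
_FULL_ORDER = ("YYYYMMDD", "HHMM", "sat", "lat", "lon", "T21", "T31", "sample", "FRP", "conf", "type")
_SHORT_ORDER = ("YYYYMMDD", "HHMM", "sat", "lat", "lon", "conf", "type")


@dataclass
class FireRecordSet:
    """A set of active-fire detections with optional anthrome labels.

    ``records`` is a DataFrame with columns :data:`RECORD_COLUMNS`;
    ``anthrome_code`` uses pandas' nullable integer dtype and
    ``anthrome_group`` is NA until :func:`assign_anthromes` runs.
    """

    records: pd.DataFrame
    n_dropped: int = 0
    n_malformed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"record table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_columns(cls, **kwargs) -> "FireRecordSet":
        n_dropped = kwargs.pop("n_dropped", 0)
        n_malformed = kwargs.pop("n_malformed", 0)
        df = pd.DataFrame(kwargs)
        if "anthrome_code" not in df:
            df["anthrome_code"] = pd.array([pd.NA] * len(df), dtype="Int64")
        if "anthrome_group" not in df:
            df["anthrome_group"] = pd.array([pd.NA] * len(df), dtype="string")
        return cls(df[list(RECORD_COLUMNS)], n_dropped=n_dropped, n_malformed=n_malformed)


@dataclass(frozen=True)
class AnthromeGrid:
    """An ESRI-ASCII-style integer class raster, row 0 northernmost."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: int
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if codes.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"codes shape {codes.shape} does not match header ({self.nrows}, {self.ncols})"
            )
        top = self.yllcorner + self.nrows * self.cellsize
        right = self.xllcorner + self.ncols * self.cellsize
        if not (-180 <= self.xllcorner and right <= 180 and -90 <= self.yllcorner and top <= 90):
            raise ValueError("grid bounds fall outside [-180, 180] x [-90, 90]")
        bad = set(np.unique(codes)) - VALID_ANTHROME_CODES - {self.nodata}
        if bad:
            raise ValueError(f"invalid anthrome codes in grid: {sorted(bad)}")

    @property
    def ytopcorner(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize


@dataclass(frozen=True)
class DailyCountSeries:
    """Consecutive daily counts starting at ``start_date``."""

    start_date: dt.date
    counts: np.ndarray
    label: str = "global"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) < 1:
            raise ValueError("counts must be a non-empty 1-d array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=len(self.counts) - 1)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=len(self.counts), freq="D")


def _parse_record_fields(fields: Mapping[str, str]):
    d = dt.datetime.strptime(fields["YYYYMMDD"], "%Y%m%d").date()
    hhmm = int(fields["HHMM"])
    minutes = (hhmm // 100) * 60 + hhmm % 100
    if not 0 <= minutes < 24 * 60:
        raise ValueError("time of day out of range")
    sat = fields["sat"].strip()[:1].upper()
    if sat not in ("T", "A"):
        raise ValueError(f"unknown satellite {fields['sat']!r}")
    lat = float(fields["lat"])
    lon = float(fields["lon"])
    conf = int(round(float(fields["conf"])))
    if not 0 <= conf <= 100:
        raise ValueError("confidence out of range")
    type_code = int(fields["type"])
    return d, minutes, sat, lat, lon, conf, type_code


def read_mcd14ml(path: str | Path) -> FireRecordSet:
    """Read fire detections from an MCD14ML-dialect delimited text file.

    Accepts comma- or whitespace-delimited lines, an optional header, and
    either the full 11-column layout (brightness, sample and FRP fields are
    ignored) or the reduced 7-column layout.  Malformed lines are counted
    and logged; records with out-of-range coordinates are dropped and
    counted.  A header lacking a required column is a hard failure.
    """
    path = Path(path)
    dates, times, sats, lats, lons, confs, types = [], [], [], [], [], [], []
    n_dropped = 0
    n_malformed = 0
    order: tuple[str, ...] | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in (line.split(",") if "," in line else line.split())]
            known = {"yyyymmdd", "date", "acq_date", "hhmm", "lat", "lon", "conf", "confidence"}
            lowered = [p.lower() for p in parts]
            if order is None and not dates and known & set(lowered):
                # header line: resolve column positions by name
                idx: dict[str, int] = {}
                for col in _REQUIRED_FILE_COLUMNS:
                    aliases = {col.lower()}
                    if col == "YYYYMMDD":
                        aliases |= {"date", "acq_date"}
                    if col == "HHMM":
                        aliases |= {"time", "acq_time"}
                    if col == "sat":
                        aliases |= {"satellite"}
                    if col == "conf":
                        aliases |= {"confidence"}
                    found = [i for i, n in enumerate(lowered) if n in aliases]
                    if not found:
                        raise ValueError(f"{path}: header is missing required column {col!r}")
                    idx[col] = found[0]
                order = tuple(idx.items())  # type: ignore[assignment]
                continue
            try:
                if order is not None:
                    fields = {col: parts[i] for col, i in order}  # type: ignore[misc]
                elif len(parts) >= len(_FULL_ORDER):
                    fields = dict(zip(_FULL_ORDER, parts))
                elif len(parts) == len(_SHORT_ORDER):
                    fields = dict(zip(_SHORT_ORDER, parts))
                else:
                    raise ValueError(f"expected {len(_SHORT_ORDER)} or {len(_FULL_ORDER)} fields")
                d, minutes, sat, lat, lon, conf, type_code = _parse_record_fields(fields)
            except (ValueError, IndexError, KeyError) as exc:
                n_malformed += 1
                logger.warning("%s:%d: malformed record skipped (%s)", path, lineno, exc)
                continue
            if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
                n_dropped += 1
                logger.warning("%s:%d: coordinates out of range, record dropped", path, lineno)
                continue
            dates.append(d)
            times.append(minutes)
            sats.append(sat)
            lats.append(lat)
            lons.append(lon)
            confs.append(conf)
            types.append(type_code)

    return FireRecordSet.from_columns(
        acq_date=pd.to_datetime(dates) if dates else pd.DatetimeIndex([]),
        acq_time=np.asarray(times, dtype=np.int64),
        satellite=pd.array(sats, dtype="string"),
        lat=np.asarray(lats, dtype=float),
        lon=np.asarray(lons, dtype=float),
        confidence=np.asarray(confs, dtype=np.int64),
        type_code=np.asarray(types, dtype=np.int64),
        n_dropped=n_dropped,
        n_malformed=n_malformed,
    )


def write_mcd14ml(recs: FireRecordSet, path: str | Path) -> None:
    """Write records in the full 11-column MCD14ML dialect with a header.

    Brightness, sample and FRP fields are cosmetic placeholders."""
    df = recs.records
    with open(path, "w") as fh:
        fh.write("YYYYMMDD,HHMM,sat,lat,lon,T21,T31,sample,FRP,conf,type\n")
        for row in df.itertuples(index=False):
            d = pd.Timestamp(row.acq_date)
            hhmm = f"{row.acq_time // 60:02d}{row.acq_time % 60:02d}"
            fh.write(
                f"{d:%Y%m%d},{hhmm},{row.satellite},{row.lat:.5f},{row.lon:.5f},"
                f"310.0,290.0,0,10.0,{row.confidence},{row.type_code}\n"
            )


def screen_records(
    recs: FireRecordSet,
    min_confidence: int = 0,
    keep_types: Iterable[int] = (0,),
) -> FireRecordSet:
    """Retain records with ``type_code in keep_types`` and confidence above threshold."""
    keep = set(keep_types)
    df = recs.records
    mask = df["type_code"].isin(keep) & (df["confidence"] >= min_confidence)
    return replace(recs, records=df[mask].reset_index(drop=True))


def read_anthrome_grid(path: str | Path) -> AnthromeGrid:
    """Read an ESRI ASCII grid (6 header lines, then rows north-first)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    expected = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")
    for i, key in enumerate(expected):
        if i >= len(lines):
            raise ValueError(f"{path}: truncated header at line {i + 1}")
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise ValueError(f"{path}: line {i + 1}: expected '{key} <value>', got {lines[i]!r}")
        header[key] = float(parts[1])
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for r in range(nrows):
        lineno = 7 + r
        if lineno - 1 >= len(lines):
            raise ValueError(f"{path}: missing data row {r + 1} (line {lineno})")
        vals = lines[lineno - 1].split()
        if len(vals) != ncols:
            raise ValueError(
                f"{path}: line {lineno}: data row {r + 1} has {len(vals)} values, expected {ncols}"
            )
        rows.append([int(v) for v in vals])
    return AnthromeGrid(
        ncols=ncols,
        nrows=nrows,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=int(header["nodata_value"]),
        codes=np.asarray(rows, dtype=int),
    )


def write_anthrome_grid(grid: AnthromeGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        for r in range(grid.nrows):
            fh.write(" ".join(str(int(v)) for v in grid.codes[r]) + "\n")


def assign_anthromes(
    recs: FireRecordSet,
    grid: AnthromeGrid,
    code_to_group: Mapping[int, str] | None = None,
) -> FireRecordSet:
    """Label each record with the anthrome class of the cell containing it.

    Cell membership uses the half-open floor rule
    ``row = floor((ytop - lat)/cellsize)``, ``col = floor((lon - xll)/cellsize)``
    so a point on a shared edge belongs to the cell south/east of the edge.
    Records outside the grid or over nodata stay unlabeled but are retained.
    Raises if the grid contains a class code absent from the mapping.
    """
    mapping = dict(ANTHROME_CODE_TO_GROUP if code_to_group is None else code_to_group)
    present = set(np.unique(grid.codes)) - {grid.nodata}
    unmapped = sorted(present - set(mapping))
    if unmapped:
        raise ValueError(f"anthrome mapping is missing codes present in the grid: {unmapped}")

    df = recs.records.copy()
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    row = np.floor((grid.ytopcorner - lat) / grid.cellsize).astype(int)
    col = np.floor((lon - grid.xllcorner) / grid.cellsize).astype(int)
    inside = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    codes = np.full(len(df), grid.nodata, dtype=int)
    codes[inside] = grid.codes[row[inside], col[inside]]
    labeled = inside & (codes != grid.nodata)

    code_col = pd.array([pd.NA] * len(df), dtype="Int64")
    group_col = pd.array([pd.NA] * len(df), dtype="string")
    code_col[labeled] = codes[labeled]
    group_col[labeled] = np.array([mapping[c] for c in codes[labeled]], dtype=object)
    df["anthrome_code"] = code_col
    df["anthrome_group"] = group_col
    return replace(recs, records=df)


def aggregate_daily(
    recs: FireRecordSet,
    start_date: dt.date,
    end_date: dt.date,
    group_by: str | None = None,
) -> dict[str, DailyCountSeries]:
    """Aggregate records to daily counts over [start_date, end_date] inclusive.

    With ``group_by="anthrome_group"`` one series per group plus an
    ``"unlabeled"`` series is returned; otherwise a single ``"global"``
    series.  Days without records count 0.
    """
    if start_date > end_date:
        raise ValueError("start_date must be <= end_date")
    if group_by not in (None, "anthrome_group"):
        raise ValueError("group_by must be None or 'anthrome_group'")
    index = pd.date_range(start_date, end_date, freq="D")
    df = recs.records
    in_window = (df["acq_date"] >= pd.Timestamp(start_date)) & (
        df["acq_date"] <= pd.Timestamp(end_date)
    )
    df = df[in_window]

    def _series(sub: pd.DataFrame, label: str) -> DailyCountSeries:
        counts = sub.groupby("acq_date").size().reindex(index, fill_value=0)
        return DailyCountSeries(start_date=start_date, counts=counts.to_numpy(), label=label)

    if group_by is None:
        return {"global": _series(df, "global")}
    out: dict[str, DailyCountSeries] = {}
    groups = df["anthrome_group"]
    for g in ANTHROME_GROUPS:
        sub = df[groups == g]
        if len(sub) or g in set(groups.dropna()):
            out[g] = _series(sub, g)
    out["unlabeled"] = _series(df[groups.isna()], "unlabeled")
    return out


def count_full_weeks(start_date: dt.date, end_date: dt.date) -> int:
    """Number of complete Monday-to-Sunday weeks wholly inside [start, end]."""
    if start_date > end_date:
        raise ValueError("start_date must be <= end_date")
    first_monday = start_date + dt.timedelta(days=(7 - start_date.weekday()) % 7)
    last_sunday = end_date - dt.timedelta(days=(end_date.weekday() + 1) % 7)
    span = (last_sunday - first_monday).days + 1
    return max(span // 7, 0)


def trim_to_full_weeks(series: DailyCountSeries) -> DailyCountSeries:
    """Trim to whole Monday-to-Sunday weeks (leading/trailing partial weeks removed)."""
    if len(series) < 7:
        raise ValueError("series shorter than one week")
    start = series.start_date
    lead = (7 - start.weekday()) % 7
    n_weeks = (len(series) - lead) // 7
    if n_weeks < 1:
        raise ValueError("fewer than 7 days remain after trimming to full weeks")
    new_start = start + dt.timedelta(days=lead)
    counts = series.counts[lead : lead + 7 * n_weeks]
    return DailyCountSeries(start_date=new_start, counts=counts, label=series.label)


WEEKDAY_NAMES = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")


def weekday_summary(series: DailyCountSeries) -> pd.DataFrame:
    """Per-weekday mean and sample sd of the counts over the weeks (Monday first)."""
    if series.start_date.weekday() != 0 or len(series) % 7:
        raise ValueError("series must be trimmed to full weeks starting Monday")
    weeks = series.counts.reshape(-1, 7)
    return pd.DataFrame(
        {
            "weekday": np.arange(1, 8),
            "name": WEEKDAY_NAMES,
            "mean": weeks.mean(axis=0),
            "sd": weeks.std(axis=0, ddof=1) if weeks.shape[0] > 1 else np.zeros(7),
        }
    )


def grid_summary(
    recs: FireRecordSet,
    cellsize: float = 0.5,
    window: tuple[dt.date, dt.date] | None = None,
    statistic: str = "count",
) -> pd.DataFrame:
    """Per-cell summary of the record set on a global grid of the given cellsize.

    ``statistic``: ``count`` (records per cell), ``min_weekday`` (weekday
    index 1..7 with the fewest records, ties to the smallest index), or
    ``modal_anthrome`` (most frequent class code, ties to the smallest code).
    Cells with no records are omitted.  Returns columns
    (row, col, lon_center, lat_center, value).
    """
    if statistic not in ("count", "min_weekday", "modal_anthrome"):
        raise ValueError(f"unknown statistic {statistic!r}")
    df = recs.records
    if window is not None:
        start, end = window
        df = df[(df["acq_date"] >= pd.Timestamp(start)) & (df["acq_date"] <= pd.Timestamp(end))]
    if statistic == "modal_anthrome":
        df = df[df["anthrome_code"].notna()]
    if not len(df):
        return pd.DataFrame(columns=["row", "col", "lon_center", "lat_center", "value"])
    row = np.floor((90.0 - df["lat"].to_numpy(float)) / cellsize).astype(int)
    col = np.floor((df["lon"].to_numpy(float) + 180.0) / cellsize).astype(int)
    work = pd.DataFrame({"row": row, "col": col})
    if statistic == "count":
        agg = work.groupby(["row", "col"]).size().rename("value").reset_index()
    elif statistic == "min_weekday":
        work["weekday"] = pd.to_datetime(df["acq_date"]).dt.weekday.to_numpy() + 1
        tallies = work.groupby(["row", "col", "weekday"]).size().rename("n").reset_index()
        # fewest records; ties resolved to the smallest weekday index
        tallies = tallies.sort_values(["row", "col", "n", "weekday"])
        agg = tallies.groupby(["row", "col"]).first().reset_index()[["row", "col", "weekday"]]
        agg = agg.rename(columns={"weekday": "value"})
    else:
        work["code"] = df["anthrome_code"].to_numpy(dtype=int)
        tallies = work.groupby(["row", "col", "code"]).size().rename("n").reset_index()
        tallies = tallies.sort_values(["row", "col", "n", "code"], ascending=[True, True, False, True])
        agg = tallies.groupby(["row", "col"]).first().reset_index()[["row", "col", "code"]]
        agg = agg.rename(columns={"code": "value"})
    agg["lon_center"] = -180.0 + (agg["col"] + 0.5) * cellsize
    agg["lat_center"] = 90.0 - (agg["row"] + 0.5) * cellsize
    return agg[["row", "col", "lon_center", "lat_center", "value"]].reset_index(drop=True)


def write_count_series_csv(series: DailyCountSeries, path: str | Path) -> None:
    """Write a series as two-column CSV (ISO date, count)."""
    pd.DataFrame({"date": series.dates().strftime("%Y-%m-%d"), "count": series.counts}).to_csv(
        path, index=False
    )


def read_count_series_csv(path: str | Path, label: str | None = None) -> DailyCountSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    dates = df["date"]
    if not (dates.diff().dropna() == pd.Timedelta(days=1)).all():
        raise ValueError(f"{path}: dates are not consecutive days")
    return DailyCountSeries(
        start_date=dates.iloc[0].date(),
        counts=df["count"].to_numpy(),
        label=label or Path(path).stem,
    )
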