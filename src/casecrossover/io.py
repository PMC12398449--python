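"""Reading, validation and summaries of date-level city time series.

The canonical in-memory container is :class:`DailySeries`: one row per
calendar day holding the all-cause death count (optionally split into the
under-65 and 65-plus age groups), 24-h mean temperature (°C), 24-h mean
relative humidity (%) and 24-h mean PM10 (µg/m³).  Dates must be strictly
consecutive calendar days; any field except ``date`` and ``deaths`` may be
missing (NaN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "SummaryStats",
    "FormatError",
    "IntegrityError",
    "DEFAULT_COLUMN_MAP",
    "read_daily_series",
    "write_daily_series",
    "summarize_series",
]


class FormatError(ValueError):
    """Input file does not have the expected shape (columns, parse failures)."""


class IntegrityError(ValueError):
    """Input parsed, but violates a series invariant (dates, counts, splits)."""


#: Default file-column names, matching the tutorial-style city files this
#: analysis consumes (``all`` is the total daily death count, ``all_0_64``
#: and ``all_65`` its optional age split).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "date": "date",
    "deaths": "all",
    "deaths_under65": "all_0_64",
    "deaths_65plus": "all_65",
    "tmean": "tmean",
    "rh": "rh",
    "pm10": "pm10",
}

_MISSING_MARKERS = ["", "NA", "NaN", "nan"]
_REQUIRED = ("date", "deaths", "tmean", "rh", "pm10")
_OPTIONAL = ("deaths_under65", "deaths_65plus")


@dataclass(frozen=True)
class DailySeries:
    """Validated daily series: consecutive dates, counts and exposures.

    Attributes
    ----------
    frame:
        DataFrame indexed 0..n-1 with columns ``date`` (datetime64),
        ``deaths`` (int), optional ``deaths_under65``/``deaths_65plus``
        (float, NaN where absent), ``tmean``, ``rh``, ``pm10`` (float,
        NaN where missing).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate_frame(self.frame)

    # -- convenience accessors -------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["date"])

    @property
    def deaths(self) -> np.ndarray:
        return self.frame["deaths"].to_numpy(dtype=np.int64)

    @property
    def tmean(self) -> np.ndarray:
        return self.frame["tmean"].to_numpy(dtype=float)

    @property
    def rh(self) -> np.ndarray:
        return self.frame["rh"].to_numpy(dtype=float)

    @property
    def pm10(self) -> np.ndarray:
        return self.frame["pm10"].to_numpy(dtype=float)

    @property
    def has_age_split(self) -> bool:
        return {"deaths_under65", "deaths_65plus"} <= set(self.frame.columns)

    def age_group_deaths(self, group: str) -> np.ndarray:
        """Death counts for ``group`` in {"under65", "65plus"}."""
        col = {"under65": "deaths_under65", "65plus": "deaths_65plus"}.get(group)
        if col is None:
            raise ValueError(f"unknown age group {group!r}")
        if col not in self.frame.columns:
            raise IntegrityError(f"series has no {col} column")
        return self.frame[col].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def _validate_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in ("date", "deaths", "tmean", "rh", "pm10") if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if len(frame) == 0:
        raise FormatError("series is empty")

    dates = pd.DatetimeIndex(frame["date"])
    dup = dates[dates.duplicated()]
    if len(dup):
        raise IntegrityError(
            "duplicate dates: " + ", ".join(d.strftime("%Y-%m-%d") for d in dup.unique()[:10])
        )
    step = np.diff(dates.values.astype("datetime64[D]").astype(int))
    if np.any(step != 1):
        bad = dates[1:][step != 1]
        raise IntegrityError(
            "non-consecutive dates at: "
            + ", ".join(d.strftime("%Y-%m-%d") for d in bad[:10])
        )

    deaths = frame["deaths"]
    if deaths.isna().any():
        raise IntegrityError("missing death counts are not allowed")
    if (deaths < 0).any():
        raise IntegrityError("negative death counts")
    if not np.allclose(deaths, np.round(deaths)):
        raise IntegrityError("death counts must be integers")

    for col in _OPTIONAL:
        if col in frame.columns and (frame[col].dropna() < 0).any():
            raise IntegrityError(f"negative counts in {col}")
    if {"deaths_under65", "deaths_65plus"} <= set(frame.columns):
        u, o = frame["deaths_under65"], frame["deaths_65plus"]
        ok = u.isna() | o.isna() | (u + o == frame["deaths"])
        if not ok.all():
            bad = dates[~ok]
            raise IntegrityError(
                "age-split counts do not sum to the total on: "
                + ", ".join(d.strftime("%Y-%m-%d") for d in bad[:10])
            )

    rh = frame["rh"].dropna()
    if ((rh < 0) | (rh > 100)).any():
        raise IntegrityError("relative humidity outside [0, 100]")
    pm = frame["pm10"].dropna()
    if (pm < 0).any():
        raise IntegrityError("negative PM10 concentrations")


@dataclass(frozen=True)
class SummaryStats:
    """Per-variable summaries of a daily series.

    Quantiles use linear interpolation between closest ranks (the numpy
    default), stated here because published IQRs rarely say which
    convention produced them.
    """

    n_days: int
    total_deaths: int
    median_deaths: float
    iqr_deaths: tuple[float, float]
    range_deaths: tuple[int, int]
    pm10: dict[str, float]
    tmean: dict[str, float]
    rh: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_days": self.n_days,
            "total_deaths": self.total_deaths,
            "median_deaths": self.median_deaths,
            "iqr_deaths": list(self.iqr_deaths),
            "range_deaths": list(self.range_deaths),
            "pm10": self.pm10,
            "tmean": self.tmean,
            "rh": self.rh,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lo, hi = self.iqr_deaths
        rlo, rhi = self.range_deaths
        lines = [
            f"days:         {self.n_days}",
            f"total deaths: {self.total_deaths}",
            f"daily deaths: median {self.median_deaths:g}, IQR {lo:g}-{hi:g}, range {rlo}-{rhi}",
        ]
        for name in ("pm10", "tmean", "rh"):
            s = getattr(self, name)
            lines.append(
                f"{name:12s}: median {s['median']:.1f}, IQR {s['q25']:.1f}-{s['q75']:.1f},"
                f" range {s['min']:.1f}-{s['max']:.1f}, missing {int(s['n_missing'])}"
            )
        return "\n".join(lines)


def read_daily_series(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = ",",
    date_format: str | None = None,
) -> DailySeries:
    """Read a delimited date-level file into a validated :class:`DailySeries`.

    Parameters
    ----------
    path:
        CSV file with a header row, one row per day.
    column_map:
        Maps internal field names (``date``, ``deaths``, ``deaths_under65``,
        ``deaths_65plus``, ``tmean``, ``rh``, ``pm10``) to file column names.
        Defaults to :data:`DEFAULT_COLUMN_MAP`; optional fields whose mapped
        column is absent are simply omitted.
    sep:
        Field delimiter.
    date_format:
        Optional explicit date format (strptime style); default parses
        ISO-8601 ``yyyy-mm-dd``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    try:
        raw = pd.read_csv(path, sep=sep, na_values=_MISSING_MARKERS, keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty or unreadable file: {path}") from exc

    for fieldname in _REQUIRED:
        if cmap[fieldname] not in raw.columns:
            raise FormatError(
                f"required column {cmap[fieldname]!r} (for {fieldname}) not found in {path}"
            )

    out = pd.DataFrame()
    try:
        out["date"] = pd.to_datetime(raw[cmap["date"]], format=date_format)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable dates in column {cmap['date']!r}: {exc}") from exc
    if raw[cmap["deaths"]].isna().any():
        raise IntegrityError("missing death counts are not allowed")
    out["deaths"] = raw[cmap["deaths"]].astype(np.int64)
    for fieldname in _OPTIONAL:
        if cmap.get(fieldname) in raw.columns:
            out[fieldname] = raw[cmap[fieldname]].astype(float)
    for fieldname in ("tmean", "rh", "pm10"):
        out[fieldname] = raw[cmap[fieldname]].astype(float)

    out = out.sort_values("date").reset_index(drop=True)
    return DailySeries(out)


def write_daily_series(series: DailySeries, path) -> None:
    """Write the canonical CSV dialect (default column names, ISO dates,
    empty field for missing) so the file round-trips through
    :func:`read_daily_series` without a column map."""
    frame = series.frame.copy()
    frame["date"] = pd.DatetimeIndex(frame["date"]).strftime("%Y-%m-%d")
    frame = frame.rename(columns=DEFAULT_COLUMN_MAP)
    frame.to_csv(path, index=False, na_rep="")


def _var_summary(x: np.ndarray) -> dict[str, float]:
    finite = x[np.isfinite(x)]
    q25, med, q75 = np.percentile(finite, [25, 50, 75])
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "min": float(finite.min()),
        "max": float(finite.max()),
        "mean": float(finite.mean()),
        "n_missing": float(len(x) - len(finite)),
    }


def summarize_series(series: DailySeries) -> SummaryStats:
    """Summaries of deaths and exposures (exact totals, interpolated quantiles)."""
    d = series.deaths.astype(float)
    q25, med, q75 = np.percentile(d, [25, 50, 75])
    return SummaryStats(
        n_days=len(series),
        total_deaths=int(series.deaths.sum()),
        median_deaths=float(med),
        iqr_deaths=(float(q25), float(q75)),
        range_deaths=(int(d.min()), int(d.max())),
        pm10=_var_summary(series.pm10),
        tmean=_var_summary(series.tmean),
        rh=_var_summary(series.rh),
    )
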