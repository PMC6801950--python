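"""Reading, cleaning and windowing of daily pollutant concentration series.

The on-disk format is a plain CSV with header ``date,PM2.5,PM10,NO2,SO2,CO,O3``,
one row per calendar day; an empty or unparseable cell is a missing value.
Concentrations are in µg/m³ except CO, which is in mg/m³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "POLLUTANTS",
    "UNITS",
    "PollutantSeries",
    "SupervisedWindows",
    "read_series",
    "read_frame",
    "write_series",
    "impute_missing",
    "split_train_test",
    "make_windows",
]

POLLUTANTS = ("PM2.5", "PM10", "NO2", "SO2", "CO", "O3")
UNITS = {p: ("mg/m^3" if p == "CO" else "ug/m^3") for p in POLLUTANTS}


@dataclass
class PollutantSeries:
    """A date-indexed univariate concentration series.

    Missing observations are stored as NaN; ``missing_mask`` derives from the
    values.  Dates must be strictly increasing with daily spacing.
    """

    pollutant: str
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANTS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must have equal length")
        if len(self.dates) == 0:
            raise ValueError("empty series")
        deltas = np.diff(self.dates.view("int64"))
        one_day = 24 * 3600 * 10**9
        if deltas.size and not np.all(deltas == one_day):
            raise ValueError("dates must be strictly increasing with daily spacing")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and np.any(observed < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def unit(self) -> str:
        return UNITS[self.pollutant]

    def __len__(self) -> int:
        return len(self.values)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.pollutant)


@dataclass
class SupervisedWindows:
    """Lag-window supervised pairs: row i holds the ``window`` values that
    immediately precede target i."""

    inputs: np.ndarray
    targets: np.ndarray
    window: int

    def __post_init__(self) -> None:
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if self.inputs.shape[0] != self.targets.size:
            raise ValueError("inputs and targets row counts differ")
        if self.inputs.shape[1] != self.window:
            raise ValueError("inputs width must equal window")

    def __len__(self) -> int:
        return self.targets.size


def read_series(path, pollutant: str, column_map: dict | None = None) -> PollutantSeries:
    """Read one pollutant column from a CSV into a chronological series.

    ``column_map`` renames file columns to the standard names (e.g.
    ``{"pm25": "PM2.5", "day": "date"}``).  Unparseable numeric cells become
    missing values.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty CSV file: {path}") from exc
    if column_map:
        frame = frame.rename(columns=column_map)
    if "date" not in frame.columns:
        raise KeyError(f"CSV {path} lacks a 'date' column")
    if pollutant not in frame.columns:
        raise KeyError(f"CSV {path} lacks a {pollutant!r} column")
    if len(frame) == 0:
        raise ValueError(f"CSV {path} contains no data rows")
    dates = pd.to_datetime(frame["date"])
    values = pd.to_numeric(frame[pollutant], errors="coerce").to_numpy(dtype=float)
    order = np.argsort(dates.to_numpy())
    return PollutantSeries(pollutant=pollutant,
                           dates=pd.DatetimeIndex(dates.to_numpy()[order]),
                           values=values[order])


def read_frame(path, column_map: dict | None = None) -> dict[str, PollutantSeries]:
    """Read all six pollutant columns; returns a dict keyed by pollutant."""
    return {p: read_series(path, p, column_map) for p in POLLUTANTS}


def write_series(series: PollutantSeries, path) -> None:
    frame = pd.DataFrame({"date": series.dates.strftime("%Y-%m-%d"),
                          series.pollutant: series.values})
    frame.to_csv(path, index=False)


def impute_missing(series: PollutantSeries) -> PollutantSeries:
    """Fill each gap with the mean of the nearest observed neighbours.

    Interior gaps take the mean of the closest observed value on each side;
    gaps at the series edges copy the single nearest observed value.
    Observed values are never altered.
    """
    values = series.values.copy()
    observed = np.where(~np.isnan(values))[0]
    if observed.size == 0:
        raise ValueError("cannot impute an all-missing series")
    for i in np.where(np.isnan(values))[0]:
        before = observed[observed < i]
        after = observed[observed > i]
        if before.size and after.size:
            values[i] = 0.5 * (values[before[-1]] + values[after[0]])
        elif before.size:
            values[i] = values[before[-1]]
        else:
            values[i] = values[after[0]]
    return PollutantSeries(series.pollutant, series.dates, values)


def split_train_test(series: PollutantSeries, boundary) -> tuple[PollutantSeries, PollutantSeries]:
    """Chronological split: train holds days up to and including ``boundary``."""
    boundary = pd.Timestamp(boundary)
    if boundary < series.dates[0] or boundary >= series.dates[-1]:
        raise ValueError(
            f"boundary {boundary.date()} must fall inside "
            f"[{series.dates[0].date()}, {series.dates[-1].date()})")
    n_train = int((series.dates <= boundary).sum())
    if n_train == 0:
        raise ValueError("training split would be empty")
    train = PollutantSeries(series.pollutant, series.dates[:n_train], series.values[:n_train])
    test = PollutantSeries(series.pollutant, series.dates[n_train:], series.values[n_train:])
    return train, test


def make_windows(series, window: int) -> SupervisedWindows:
    """Build lag-window supervised pairs from a series or a plain array."""
    if isinstance(series, PollutantSeries):
        values = series.values
    else:
        values = np.asarray(series, dtype=float).ravel()
    if window < 1:
        raise ValueError("window must be a positive integer")
    if window >= values.size:
        raise ValueError(f"window {window} must be smaller than series length {values.size}")
    n_rows = values.size - window
    idx = np.arange(window)[None, :] + np.arange(n_rows)[:, None]
    return SupervisedWindows(inputs=values[idx], targets=values[window:], window=window)
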