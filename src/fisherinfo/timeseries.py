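"""Multivariate time-series container and delimited-table / GISTEMP readers.

The analysis operates on a ``T x n`` matrix of system observations: one row
per time step ``t_j``, one column per measured variable ``y_i``, so that the
system state at time ``t_j`` is the vector ``(y_1(t_j), ..., y_n(t_j))``.
Time labels are opaque ordered identifiers (typically integer years); the
method itself only requires sequential order, so irregular calendar gaps are
accepted with a warning rather than rejected.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)

MONTH_NAMES = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

#: regex for missing-value markers in GISTEMP-style tables ("***", "****", ...)
_MISSING_RE = re.compile(r"^\*+$")


@dataclass
class TimeSeriesMatrix:
    """A ``T x n`` multivariate time series with ordered time labels.

    Parameters
    ----------
    time_labels : array-like of shape (T,)
        Strictly increasing time identifiers (e.g. integer years).
    variable_names : sequence of str, length n
        One name per variable column.
    values : ndarray of shape (T, n)
        Observations; must be finite (missing data are resolved at ingestion
        by dropping whole rows).
    """

    time_labels: np.ndarray
    variable_names: list[str]
    values: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.time_labels = np.asarray(self.time_labels)
        self.values = np.asarray(self.values, dtype=float)
        self.variable_names = [str(v) for v in self.variable_names]
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D (T x n) array")
        T, n = self.values.shape
        if n < 1 or T < 1:
            raise InputError("need at least one time step and one variable")
        if len(self.variable_names) != n:
            raise InputError(
                f"{len(self.variable_names)} variable names for {n} columns")
        if len(self.time_labels) != T:
            raise InputError(
                f"{len(self.time_labels)} time labels for {T} rows")
        diffs = np.diff(self.time_labels.astype(float))
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise InputError(
                "time labels must be strictly increasing; violation at row "
                f"{bad} (label {self.time_labels[bad]!r})")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite value at time {self.time_labels[r]!r}, "
                f"variable {self.variable_names[c]!r}")
        if len(set(np.diff(self.time_labels.astype(float)))) > 1:
            warnings.warn(
                "time labels are not equally spaced; the analysis treats "
                "rows as sequential steps", stacklevel=2)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_frame(self, time_column: str = "time") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, time_column, self.time_labels)
        return df

    def index_of_label(self, label) -> int:
        """Row index of a time label; raises :class:`InputError` if absent."""
        hits = np.nonzero(self.time_labels == np.asarray(label))[0]
        if len(hits) == 0:
            raise InputError(f"time label {label!r} not present in series")
        return int(hits[0])

    def slice_period(self, start, end) -> "TimeSeriesMatrix":
        """Inclusive sub-series between two existing time labels."""
        i, j = self.index_of_label(start), self.index_of_label(end)
        if j < i:
            raise InputError(f"period end {end!r} precedes start {start!r}")
        return TimeSeriesMatrix(self.time_labels[i:j + 1],
                                self.variable_names,
                                self.values[i:j + 1], name=self.name)


def read_timeseries_table(path, time_column: str = "time") -> TimeSeriesMatrix:
    """Read a delimited table (CSV with header) into a :class:`TimeSeriesMatrix`.

    The ``time_column`` supplies the time labels; every other column is taken
    as a numeric system variable, in file order.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"input file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise InputError(f"cannot parse {path}: {exc}") from None
    if time_column not in df.columns:
        raise InputError(
            f"time column {time_column!r} not in header {list(df.columns)}")
    labels = df[time_column].to_numpy()
    if pd.Series(labels).duplicated().any():
        dup = pd.Series(labels)[pd.Series(labels).duplicated()].iloc[0]
        raise InputError(f"duplicate time label {dup!r} in {path}")
    var_cols = [c for c in df.columns if c != time_column]
    if not var_cols:
        raise InputError(f"no variable columns in {path}")
    numeric = df[var_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r = int(np.argwhere(bad.to_numpy())[0][0])
        c = bad.columns[int(np.argwhere(bad.to_numpy())[0][1])]
        raise InputError(
            f"non-numeric or empty cell at row {r + 1} (time "
            f"{labels[r]!r}), column {c!r} of {path}")
    return TimeSeriesMatrix(labels, var_cols, numeric.to_numpy(float),
                            name=str(path))


def write_timeseries_table(ts: TimeSeriesMatrix, path,
                           time_column: str = "time") -> None:
    """Write a series as CSV, round-trippable by :func:`read_timeseries_table`."""
    ts.to_frame(time_column).to_csv(path, index=False, float_format="%.12g")


def read_gistemp_monthly(path) -> TimeSeriesMatrix:
    """Read a GISTEMP-style monthly-anomaly table (years x Jan..Dec).

    Each month is treated as one system variable, giving 12 variables per
    yearly time step. Values are kept in the file's units (the published
    tables print anomalies in 0.01 degC relative to a fixed base period).
    Missing markers (``***`` etc.) cause the whole year to be excluded, since
    state binning needs all variables at a point; exclusions are logged.
    """
    try:
        with open(path) as fh:
            lines = fh.read().splitlines()
    except FileNotFoundError:
        raise InputError(f"input file not found: {path}") from None

    header_idx = None
    delim = ","
    for i, line in enumerate(lines):
        toks = [t.strip() for t in re.split(r"[,\s]+", line.strip()) if t.strip()]
        if toks and toks[0].lower() == "year" and "Jan" in toks and "Dec" in toks:
            header_idx = i
            delim = "," if "," in line else None  # None = whitespace
            header = toks
            break
    if header_idx is None:
        raise InputError(
            f"malformed GISTEMP table {path}: no 'Year,Jan,...,Dec' header")
    month_pos = []
    for m in MONTH_NAMES:
        if m not in header:
            raise InputError(f"malformed header in {path}: month {m} missing")
        month_pos.append(header.index(m))
    year_pos = header.index("Year")

    years, rows, excluded = [], [], []
    for line in lines[header_idx + 1:]:
        raw = line.strip()
        if not raw:
            continue
        toks = ([t.strip() for t in raw.split(",")] if delim == ","
                else raw.split())
        if not toks or not re.fullmatch(r"-?\d{3,4}", toks[0].strip()):
            continue  # repeated headers / footers in real GISTEMP files
        year = int(toks[year_pos])
        vals, missing = [], False
        for pos in month_pos:
            tok = toks[pos] if pos < len(toks) else ""
            if not tok or _MISSING_RE.match(tok) or tok.upper() in ("NA", "N/A"):
                missing = True
                break
            try:
                vals.append(float(tok))
            except ValueError:
                missing = True
                break
        if missing:
            excluded.append(year)
        else:
            years.append(year)
            rows.append(vals)
    if excluded:
        logger.warning("excluded %d incomplete year(s): %s",
                       len(excluded), excluded)
    if not rows:
        raise InputError(f"no complete year rows in {path}")
    return TimeSeriesMatrix(np.array(years), MONTH_NAMES,
                            np.array(rows), name=str(path))


def write_fi_table(series, path) -> None:
    """Write an FI series as CSV (columns time_label, fi, n_states, tl_mode)."""
    if len(series) == 0:
        raise InputError("cannot write an empty FI series")
    series.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_fi_table(path):
    """Read back a CSV written by :func:`write_fi_table`."""
    from .windowing import FIEntry, FISeries
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"FI table not found: {path}") from None
    required = {"time_label", "fi", "n_states", "tl_mode"}
    if not required.issubset(df.columns):
        raise InputError(
            f"{path} is not an FI table (needs columns {sorted(required)})")
    entries = [FIEntry(row.time_label, float(row.fi), int(row.n_states),
                       str(row.tl_mode))
               for row in df.itertuples()]
    return FISeries(entries)
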