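"""Model/Results interface over the FI pipeline.

``FisherInformationModel`` holds the data and the analysis settings (size of
state, window geometry, tightening mode); ``fit()`` runs the sliding-window
computation and returns a ``FisherInformationResults`` carrying the FI
series with summaries, trend labels and plotting. The pattern mirrors the
model-object convention of statistical packages: construct from data, fit,
inspect a results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import TighteningSpec
from .exceptions import InputError
from .sizing import SizeOfState, estimate_size_of_state
from .timeseries import TimeSeriesMatrix, write_fi_table
from .windowing import (FISeries, RegimeSummary, WindowSpec, block_average,
                        classify_trend, compute_fi_series, regime_summary)


class FisherInformationModel:
    """Sliding-window Fisher information stability model of a multivariate series.

    Parameters
    ----------
    data : TimeSeriesMatrix
        The observations (use :meth:`from_dataframe` for a pandas frame).
    deltas : sequence of float or SizeOfState, optional
        Explicit size of state per variable. Exactly one of ``deltas`` and
        ``stable_period`` must be given.
    stable_period : (start, end), optional
        Inclusive time-label range from which to estimate the size of state
        as ``k`` sample standard deviations per variable.
    k : float
        Chebyshev multiplier for estimation (default 2: >= 75% coverage).
    window : int
        Window width in time steps (>= 8 recommended).
    increment : int
        Window advance per step (default 1).
    tightening : {"strict", "averaged"}
        Strict all-variables binning, or FI averaged over the per-window
        tightening-level set.

    Examples
    --------
    >>> from fisherinfo import FisherInformationModel, synthetic
    >>> ts = synthetic.two_regime_series(seed=1)
    >>> res = FisherInformationModel(ts, deltas=[1.0, 1.0], window=8).fit()
    >>> res.fi_series.fi_values[0]  # doctest: +SKIP
    """

    def __init__(self, data: TimeSeriesMatrix, *, deltas=None,
                 stable_period=None, k: float = 2.0, window: int = 8,
                 increment: int = 1, tightening: str = "strict"):
        if not isinstance(data, TimeSeriesMatrix):
            raise InputError(
                "data must be a TimeSeriesMatrix (see from_dataframe)")
        self.data = data
        self.window_spec = WindowSpec(window, increment)
        self.tightening = TighteningSpec(tightening)
        if (deltas is None) == (stable_period is None):
            raise InputError(
                "give exactly one of deltas (explicit size of state) or "
                "stable_period (estimate it)")
        if deltas is not None:
            self.size_of_state = (deltas if isinstance(deltas, SizeOfState)
                                  else SizeOfState(np.asarray(deltas, float)))
        else:
            self.size_of_state = estimate_size_of_state(data, stable_period, k)
        if len(self.size_of_state) != data.n_variables:
            raise InputError(
                f"size of state has {len(self.size_of_state)} entries for "
                f"{data.n_variables} variables")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_column: str = "time",
                       **kwargs) -> "FisherInformationModel":
        """Build from a DataFrame with a time column and numeric variables."""
        if time_column not in df.columns:
            raise InputError(f"time column {time_column!r} not in frame")
        var_cols = [c for c in df.columns if c != time_column]
        ts = TimeSeriesMatrix(df[time_column].to_numpy(), var_cols,
                              df[var_cols].to_numpy(float))
        return cls(ts, **kwargs)

    def fit(self, smoothing_block: int | None = None) -> "FisherInformationResults":
        """Compute the FI series (optionally block-averaged) and wrap it."""
        series = compute_fi_series(self.data, self.size_of_state,
                                   self.window_spec, self.tightening)
        if smoothing_block and smoothing_block > 1:
            series = block_average(series, smoothing_block)
        return FisherInformationResults(self, series,
                                        smoothing_block=smoothing_block)


class FisherInformationResults:
    """Fitted FI series plus summaries, trend labels, export and plotting."""

    def __init__(self, model: FisherInformationModel, fi_series: FISeries,
                 smoothing_block: int | None = None):
        self.model = model
        self.fi_series = fi_series
        self.smoothing_block = smoothing_block

    # -- accessors ---------------------------------------------------------
    @property
    def fi(self) -> np.ndarray:
        return self.fi_series.fi_values

    @property
    def time_labels(self) -> np.ndarray:
        return self.fi_series.time_labels

    def to_frame(self) -> pd.DataFrame:
        return self.fi_series.to_frame()

    def save(self, path) -> None:
        """Write the FI series as CSV."""
        write_fi_table(self.fi_series, path)

    # -- summaries ---------------------------------------------------------
    def regime_summary(self, period) -> RegimeSummary:
        """Mean/sd of FI over an inclusive (start, end) label range."""
        return regime_summary(self.fi_series, period)

    def classify_trend(self, slope_tolerance: float = 0.05,
                       drop_threshold: float = 2.0,
                       span: int = 8) -> list[str]:
        return classify_trend(self.fi_series, slope_tolerance,
                              drop_threshold, span)

    def summary(self, periods=None) -> str:
        """Human-readable run summary, optionally with per-period regimes."""
        m = self.model
        d = m.size_of_state
        full = regime_summary(
            self.fi_series,
            (self.time_labels[0], self.time_labels[-1]))
        lines = [
            "Fisher Information Stability Analysis",
            "=" * 53,
            f"Series:            {m.data.name or '<in-memory>'}",
            f"Time steps (T):    {m.data.n_steps}"
            f"   Variables (n): {m.data.n_variables}",
            f"Window (w, h):     ({m.window_spec.width}, "
            f"{m.window_spec.increment})",
            f"Tightening:        {m.tightening.mode}",
            f"Smoothing block:   {self.smoothing_block or 'off'}",
            "Size of state:     "
            + np.array2string(d.deltas, precision=4, separator=", "),
        ]
        if d.k is not None:
            lines.append(
                f"  (estimated: k = {d.k:g}, Chebyshev coverage >= "
                f"{d.coverage:.2f}, stable period "
                f"{d.stable_period[0]}..{d.stable_period[1]})")
        lines += [
            "-" * 53,
            f"FI entries:        {len(self.fi_series)} "
            f"(labels {self.time_labels[0]}..{self.time_labels[-1]})",
            f"Overall mu_FI:     {full.mu_fi:.3f}   sigma_FI: "
            f"{full.sigma_fi:.3f}",
        ]
        for period in periods or []:
            s = self.regime_summary(period)
            lines.append(
                f"Period {s.period[0]}..{s.period[1]}:  mu_FI = "
                f"{s.mu_fi:.3f}  sigma_FI = {s.sigma_fi:.3f}  (n = {s.n})")
        lines.append("=" * 53)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot(self, ax=None, show_data: bool = False):
        """FI against time (optionally with the raw variables above it)."""
        from . import plotting
        return plotting.plot_fi(self, ax=ax, show_data=show_data)
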