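"""Sliding-window FI series, smoothing, regime summaries and trend labels.

One FI value is computed per window of ``w`` consecutive time steps and
attributed to the window's last time step, so only past data enter each
value. The window then advances by ``h`` steps; incomplete trailing windows
are dropped. For a series of ``T`` steps this yields
``floor((T - w)/h) + 1`` entries.

Interpretation follows the sustainable-regimes reading of the index: a
regime is a period of nearly constant non-zero FI (high mean, low sd); a
steady decline warns of loss of order; a sharp drop signals a regime shift,
with intensity related to the depth of the drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .binning import TighteningSpec, bin_window, tl_set_for_window
from .exceptions import InputError
from .fi import fi_of_partition
from .sizing import SizeOfState
from .timeseries import TimeSeriesMatrix


@dataclass
class WindowSpec:
    """Moving-window geometry: width ``w`` and increment ``h`` in time steps.

    The increment must not exceed the width, so consecutive windows overlap
    and behaviour spanning a window boundary is still captured; ``h == w``
    (abutting windows) is allowed with a warning. Widths below 8 steps are
    legal but warned against — small windows give noisy state counts.
    """

    width: int
    increment: int = 1

    def __post_init__(self) -> None:
        if self.width < 2:
            raise InputError(f"window width must be >= 2, got {self.width}")
        if self.increment < 1:
            raise InputError(
                f"window increment must be >= 1, got {self.increment}")
        if self.increment > self.width:
            raise InputError(
                f"increment {self.increment} exceeds window width "
                f"{self.width}; windows would skip data")
        if self.increment == self.width:
            warnings.warn("increment equals window width; windows do not "
                          "overlap", stacklevel=2)
        if self.width < 8:
            warnings.warn(
                f"window width {self.width} is below the recommended "
                "minimum of 8 time steps", stacklevel=2)


@dataclass
class FIEntry:
    """One window's result, attributed to the window's last time label."""

    time_label: object
    fi: float
    n_states: int
    tl_mode: str
    tl_levels: tuple = field(default=(), compare=False)


@dataclass
class FISeries:
    """Ordered sequence of per-window FI entries."""

    entries: list[FIEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def time_labels(self) -> np.ndarray:
        return np.array([e.time_label for e in self.entries])

    @property
    def fi_values(self) -> np.ndarray:
        return np.array([e.fi for e in self.entries], dtype=float)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_label": [e.time_label for e in self.entries],
            "fi": [e.fi for e in self.entries],
            "n_states": [e.n_states for e in self.entries],
            "tl_mode": [e.tl_mode for e in self.entries],
        })

    def slice_period(self, start, end) -> "FISeries":
        labels = self.time_labels.astype(float)
        lo, hi = float(start), float(end)
        picked = [e for e, t in zip(self.entries, labels) if lo <= t <= hi]
        return FISeries(picked)


@dataclass
class RegimeSummary:
    """Mean and sample sd of FI over an inclusive label range.

    A stable regime shows a relatively high and steady mean FI (``mu_fi``)
    with low ``sigma_fi`` compared with other periods.
    """

    period: tuple
    mu_fi: float
    sigma_fi: float
    n: int


def compute_fi_series(ts: TimeSeriesMatrix, deltas: SizeOfState,
                      win: WindowSpec,
                      tl: TighteningSpec | None = None) -> FISeries:
    """Slide the window through the series and compute FI per window.

    In ``strict`` mode each window is binned at TL = 1. In ``averaged`` mode
    each window is binned at every level of its own TL set (from strict down
    to the loosest level still resolving > 1 state) and the mean FI over
    those levels is reported. ``n_states`` always reports the strict-mode
    state count.
    """
    tl = tl or TighteningSpec("strict")
    if len(deltas) != ts.n_variables:
        raise InputError(
            f"size of state has {len(deltas)} entries for "
            f"{ts.n_variables} variables")
    T, w, h = ts.n_steps, win.width, win.increment
    if T < w:
        raise InputError(
            f"series has {T} steps; at least the window width {w} is "
            "required")
    entries = []
    for start in range(0, T - w + 1, h):
        pts = ts.values[start:start + w]
        strict_part = bin_window(pts, deltas, 1.0)
        if tl.mode == "strict":
            fi = fi_of_partition(strict_part)
            levels = (1.0,)
            mode = "strict"
        else:
            levels = tuple(tl_set_for_window(pts, deltas))
            fis = [fi_of_partition(bin_window(pts, deltas, lev))
                   if lev != 1.0 else fi_of_partition(strict_part)
                   for lev in levels]
            fi = float(np.mean(fis))
            mode = "averaged"
        entries.append(FIEntry(ts.time_labels[start + w - 1], fi,
                               strict_part.m, mode, levels))
    return FISeries(entries)


def block_average(series: FISeries, b: int) -> FISeries:
    """Smooth by non-overlapping block means (a high-frequency filter).

    Each block of ``b`` consecutive FI values is replaced by its mean, which
    acts as the representative value for every entry in the block; a
    trailing partial block is averaged over its own length. Labels and state
    counts are preserved; ``b = 1`` returns the series unchanged.
    """
    if b < 1:
        raise InputError(f"block size must be >= 1, got {b}")
    out = []
    for i in range(0, len(series), b):
        block = series.entries[i:i + b]
        mean = float(np.mean([e.fi for e in block]))
        out.extend(replace(e, fi=mean) for e in block)
    return FISeries(out)


def regime_summary(series: FISeries, period) -> RegimeSummary:
    """Mean and sample sd of FI over an inclusive time-label period."""
    start, end = period
    sub = series.slice_period(start, end)
    if len(sub) == 0:
        raise InputError(
            f"no FI entries in period {start!r}..{end!r}")
    vals = sub.fi_values
    sigma = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return RegimeSummary((start, end), float(np.mean(vals)), sigma, len(vals))


def classify_trend(series: FISeries, slope_tolerance: float = 0.05,
                   drop_threshold: float = 2.0, span: int = 8) -> list[str]:
    """Label each entry {stable, increasing, declining, sharp_drop}.

    Over a trailing assessment span of up to ``span`` entries ending at each
    entry, the least-squares slope of FI against entry index decides the
    label: within ``+-slope_tolerance`` per step -> ``stable``; above ->
    ``increasing``; below -> ``declining``. A single-step decrease exceeding
    ``drop_threshold`` overrides the slope and labels the entry
    ``sharp_drop`` (the regime-shift signal). The thresholds are heuristics;
    the underlying interpretation rules are qualitative.
    """
    if len(series) < 2:
        raise InputError("trend classification needs at least 2 entries")
    if span > len(series):
        raise InputError(
            f"assessment span {span} exceeds series length {len(series)}")
    if span < 2:
        raise InputError(f"assessment span must be >= 2, got {span}")
    fi = series.fi_values
    labels = []
    for j in range(len(fi)):
        if j >= 1 and fi[j - 1] - fi[j] > drop_threshold:
            labels.append("sharp_drop")
            continue
        lo = max(0, j - span + 1)
        seg = fi[lo:j + 1]
        if len(seg) < 2:
            labels.append("stable")
            continue
        slope = np.polyfit(np.arange(len(seg)), seg, 1)[0]
        if slope > slope_tolerance:
            labels.append("increasing")
        elif slope < -slope_tolerance:
            labels.append("declining")
        else:
            labels.append("stable")
    return labels
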