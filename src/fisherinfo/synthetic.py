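"""Piecewise-stationary synthetic series with controlled regime shifts.

Each regime holds the per-variable means fixed and adds independent Gaussian
noise; a regime shift is a step change in the mean vector. This is the
minimal data-generating process the index is designed to detect — windows
inside a regime see one (or few) states and high FI, windows straddling a
shift see the state split and FI dip. Gaussian noise is a deliberate,
light-tailed choice; the Chebyshev sizing rule is distribution-free, so
nothing downstream depends on normality.

All generation is seeded; there is no unseeded API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .timeseries import TimeSeriesMatrix


@dataclass
class RegimeSpec:
    """One stationary regime: inclusive step range, mean vector, noise sds."""

    start: int
    end: int
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_1d(np.asarray(self.sds, dtype=float))
        if self.end < self.start:
            raise InputError(
                f"regime end {self.end} precedes start {self.start}")
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise InputError("means and sds must be 1-D vectors of equal length")
        if np.any(self.sds < 0):
            raise InputError("noise scales must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def generate_series(regimes: list[RegimeSpec], seed: int,
                    variable_names: list[str] | None = None) -> TimeSeriesMatrix:
    """Draw a multivariate series from a sequence of contiguous regimes.

    Successive regimes must tile the time axis exactly (each starts one step
    after the previous ends). Time labels are the regime step ranges
    themselves. Fully reproducible from ``seed``.
    """
    if not regimes:
        raise InputError("at least one regime is required")
    n = len(regimes[0].means)
    for r in regimes:
        if len(r.means) != n:
            raise InputError(
                "all regimes must have the same number of variables")
    for prev, cur in zip(regimes, regimes[1:]):
        if cur.start != prev.end + 1:
            raise InputError(
                f"regimes must be contiguous and non-overlapping: "
                f"{prev.end} -> {cur.start}")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for r in regimes:
        noise = rng.standard_normal((r.length, n)) * r.sds
        rows.append(r.means + noise)
        labels.extend(range(r.start, r.end + 1))
    names = variable_names or [f"y{i + 1}" for i in range(n)]
    return TimeSeriesMatrix(np.array(labels), names, np.vstack(rows),
                            name=f"synthetic(seed={seed})")


def two_regime_series(n_steps: int = 120, change_point: int = 60,
                      n_variables: int = 2, mean_shift: float = 10.0,
                      noise_sd: float = 0.1, seed: int = 0) -> TimeSeriesMatrix:
    """Convenience scenario: one mean step of ``mean_shift`` at ``change_point``.

    ``change_point`` is the first step of the second regime (1-based labels
    run ``1..n_steps``).
    """
    if not 1 < change_point <= n_steps:
        raise InputError("change point must lie inside the series")
    means_a = np.zeros(n_variables)
    means_b = np.full(n_variables, mean_shift)
    sds = np.full(n_variables, noise_sd)
    return generate_series(
        [RegimeSpec(1, change_point - 1, means_a, sds),
         RegimeSpec(change_point, n_steps, means_b, sds)], seed=seed)
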