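"""Size-of-state estimation via Chebyshev's inequality.

Two observations of a variable are indistinguishable when they differ by no
more than that variable's measurement uncertainty ``delta_y_i``. When the
uncertainty is not reported with the data, it is estimated from a relatively
stable period of the series as ``k`` sample standard deviations: by
Chebyshev's inequality at least ``1 - 1/k**2`` of any distribution lies
within ``k`` s.d. of its mean, so ``k = 2`` guarantees 75% coverage
regardless of the noise distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .timeseries import TimeSeriesMatrix


@dataclass
class SizeOfState:
    """Per-variable uncertainty ``delta_y_i`` defining the state hyper-rectangle.

    ``deltas`` are in each variable's own units. A zero delta is legal (only
    exactly equal values then bin together) but usually signals a degenerate
    variable, so it triggers a warning.
    """

    deltas: np.ndarray
    #: metadata: Chebyshev k and guaranteed coverage, when estimated
    k: float | None = None
    coverage: float | None = None
    stable_period: tuple | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.deltas = np.atleast_1d(np.asarray(self.deltas, dtype=float))
        if self.deltas.ndim != 1:
            raise InputError("deltas must be a 1-D vector")
        if np.any(self.deltas < 0) or not np.all(np.isfinite(self.deltas)):
            raise InputError("deltas must be finite and non-negative")
        if np.any(self.deltas == 0):
            warnings.warn(
                "size of state is 0 for variable(s) "
                f"{list(np.nonzero(self.deltas == 0)[0])}; only exactly "
                "equal values will share a state", stacklevel=2)

    def __len__(self) -> int:
        return len(self.deltas)


def estimate_size_of_state(ts: TimeSeriesMatrix, stable_period,
                           k: float = 2.0) -> SizeOfState:
    """Estimate ``delta_y_i = k * sd_i`` over a designated stable period.

    Parameters
    ----------
    ts : TimeSeriesMatrix
        The full series.
    stable_period : (start, end)
        Inclusive time-label range judged stable by the analyst (the method
        leaves this choice to domain knowledge).
    k : float
        Chebyshev multiplier; the default 2 guarantees at least
        ``1 - 1/4 = 75%`` coverage. The sample (T-1 denominator) standard
        deviation is used.
    """
    if k <= 0:
        raise InputError(f"k must be positive, got {k}")
    start, end = stable_period
    sub = ts.slice_period(start, end)
    if sub.n_steps < 2:
        raise InputError(
            f"stable period {start!r}..{end!r} has {sub.n_steps} point(s); "
            "at least 2 are needed for a standard deviation")
    sd = np.std(sub.values, axis=0, ddof=1)
    return SizeOfState(k * sd, k=k, coverage=1.0 - 1.0 / k ** 2,
                       stable_period=(start, end))
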