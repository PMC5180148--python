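"""Discrete Fisher information of a binned window.

With the window partitioned into ``m`` states, the probability of state
``i`` is its point count over the window size, and its amplitude is
``q_i = sqrt(p_i)`` (the amplitude form avoids dividing by small
probabilities). The index is

    FI = 4 * [ (0 - q_1)^2 + sum_{i=1}^{m-1} (q_i - q_{i+1})^2 + (q_m - 0)^2 ]

with states taken in binning discovery order and one zero amplitude
prepended and appended. The zero boundaries make FI strictly positive, with
the maximum FI = 8 attained exactly when all points share one state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import StatePartition
from .exceptions import InputError


@dataclass
class ProbabilityProfile:
    """State probabilities ``p`` and amplitudes ``q`` for one window."""

    p: np.ndarray
    window_size: int

    def __post_init__(self) -> None:
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.window_size < 1:
            raise InputError("window_size must be >= 1")
        if np.any(self.p < 0):
            raise InputError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise InputError(
                f"probabilities sum to {self.p.sum()!r}, not 1")
        # counts-based p: each state holds at least one of the w points
        if np.any(self.p < 1.0 / self.window_size - 1e-12):
            raise InputError(
                "every state probability must be >= 1/window_size")

    @property
    def q(self) -> np.ndarray:
        """Amplitudes ``sqrt(p)``, in discovery order."""
        return np.sqrt(self.p)

    @property
    def m(self) -> int:
        return len(self.p)


def state_probabilities(partition: StatePartition) -> ProbabilityProfile:
    """Probability of each state: point count over window size, discovery order."""
    counts = partition.counts()
    return ProbabilityProfile(counts / partition.n_points,
                              window_size=partition.n_points)


def fisher_information(profile: ProbabilityProfile) -> float:
    """Evaluate the discrete FI of one window's probability profile."""
    q = np.concatenate(([0.0], profile.q, [0.0]))
    return float(4.0 * np.sum(np.diff(q) ** 2))


def fi_of_partition(partition: StatePartition) -> float:
    """Convenience: FI straight from a state partition."""
    return fisher_information(state_probabilities(partition))
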