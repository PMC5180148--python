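"""Greedy hyper-rectangle binning of a time window into discrete states.

A state is an ``n``-dimensional hyper-rectangular box whose half-sides are
the per-variable uncertainties ``delta_y_i``, centred on a founding point.
Binning is greedy and time-ordered: the earliest unbinned point founds the
next state and immediately captures every later unbinned point lying in its
box; captured points are never reassigned, even if a later box also covers
them. Membership is always tested against the founding point (the centre),
never pairwise between members — two members of one state may differ by more
than ``delta_y_i`` as long as each is within ``delta_y_i`` of the centre.

The tightening level (TL) relaxes the box test: a point joins a state when
at least a fraction ``tl`` of its variables satisfy the size-of-state
criterion (TL = 1 is the strict, all-variables test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .sizing import SizeOfState

#: slack for comparing a variable-count fraction against a TL fraction;
#: levels are multiples of 1/n, so this only absorbs float representation.
_TL_EPS = 1e-9


@dataclass
class TighteningSpec:
    """Tightening mode for a run.

    mode ``"strict"`` bins with TL = 1 only. mode ``"averaged"`` bins each
    window at every TL in a descending grid of multiples of ``1/n``, from 1
    down to the lowest level at which the window still resolves more than
    one state, and reports the mean FI over those levels.
    """

    mode: str = "strict"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "averaged"):
            raise InputError(
                f"tightening mode must be 'strict' or 'averaged', "
                f"got {self.mode!r}")


@dataclass
class StatePartition:
    """Result of binning one window.

    assignments : 1-based state index per in-window point, in time order.
    center_indices : index (within the window) of each state's founding point.
    States are numbered in discovery order; the founding point of state ``s``
    is always assigned to ``s``.
    """

    assignments: np.ndarray
    center_indices: np.ndarray

    @property
    def m(self) -> int:
        """Number of states."""
        return len(self.center_indices)

    @property
    def n_points(self) -> int:
        return len(self.assignments)

    def members(self, state: int) -> np.ndarray:
        """Window indices of the points in 1-based ``state``."""
        return np.nonzero(self.assignments == state)[0]

    def counts(self) -> np.ndarray:
        """Point count per state, in discovery order."""
        return np.bincount(self.assignments, minlength=self.m + 1)[1:]


def same_state(center, point, deltas: SizeOfState | np.ndarray,
               tl: float = 1.0) -> bool:
    """Indistinguishability test of ``point`` against a state ``center``.

    True iff at least a fraction ``tl`` of the variables ``i`` satisfy
    ``|center_i - point_i| <= delta_i`` (inclusive comparison).
    """
    d = deltas.deltas if isinstance(deltas, SizeOfState) else np.asarray(deltas, float)
    c = np.asarray(center, dtype=float)
    p = np.asarray(point, dtype=float)
    if not (c.shape == p.shape == d.shape) or c.ndim != 1:
        raise InputError(
            f"length mismatch: center {c.shape}, point {p.shape}, "
            f"deltas {d.shape}")
    if not 0 < tl <= 1:
        raise InputError(f"tightening level must be in (0, 1], got {tl}")
    n_within = int(np.sum(np.abs(c - p) <= d))
    return n_within >= tl * len(d) - _TL_EPS


def bin_window(points, deltas: SizeOfState | np.ndarray,
               tl: float = 1.0) -> StatePartition:
    """Partition a window's points into states by the greedy procedure."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.size == 0:
        raise InputError("cannot bin an empty window")
    d = deltas.deltas if isinstance(deltas, SizeOfState) else np.asarray(deltas, float)
    if pts.shape[1] != len(d):
        raise InputError(
            f"points have {pts.shape[1]} variables but deltas has {len(d)}")
    if not 0 < tl <= 1:
        raise InputError(f"tightening level must be in (0, 1], got {tl}")

    w, n = pts.shape
    need = tl * n - _TL_EPS
    assignments = np.zeros(w, dtype=int)
    centers: list[int] = []
    for i in range(w):
        if assignments[i]:
            continue
        centers.append(i)
        state = len(centers)
        assignments[i] = state
        free = assignments[i + 1:] == 0
        if free.any():
            cand = np.nonzero(free)[0] + i + 1
            within = np.sum(np.abs(pts[cand] - pts[i]) <= d, axis=1) >= need
            assignments[cand[within]] = state
    return StatePartition(assignments, np.array(centers, dtype=int))


def tl_grid(n: int) -> list[float]:
    """Descending TL grid for ``n`` variables: ``n/n, (n-1)/n, ..., 1/n``."""
    return [(n - i) / n for i in range(n)]


def tl_set_for_window(points, deltas, grid=None) -> list[float]:
    """TL level set for one window: the contiguous prefix of the grid, from
    the strict level 1.0 down to (and including) the lowest level at which
    binning still yields more than one state.

    If even the strict level yields a single state, ``[1.0]`` is returned:
    a one-state window carries no level to relax towards.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if grid is None:
        grid = tl_grid(pts.shape[1])
    grid = list(grid)
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise InputError("TL grid must be strictly descending")
    levels = []
    for tl in grid:
        if bin_window(pts, deltas, tl).m > 1:
            levels.append(tl)
        else:
            break
    return levels if levels else [grid[0]]
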