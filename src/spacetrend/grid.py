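"""The mission time grid.

All analyses operate on series collapsed to a small common grid of
mission-anchored bins, labeled by a representative day relative to launch:
two pre-flight bins (-180, -45 d), three in-flight bins (33, 82, 132 d), the
return bin (165 d) and two post-return bins (195, 225 d).  The -45 d bin is
the pre-flight baseline every series is differenced against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical bin labels, in days relative to launch.
MISSION_GRID_DAYS: tuple[float, ...] = (-180.0, -45.0, 33.0, 82.0, 132.0, 165.0, 195.0, 225.0)

#: Default extent of the study window, days relative to launch.
DEFAULT_WINDOW: tuple[float, float] = (-200.0, 240.0)

#: Index of the pre-flight baseline bin (-45 d).
BASELINE_INDEX: int = 1


@dataclass(frozen=True)
class TimeGrid:
    """Ordered time bins with half-open day boundaries.

    Parameters
    ----------
    labels
        Strictly increasing representative day per bin.
    window
        (start, end) days of the study window.  Bin edges are midpoints
        between adjacent labels, extended to the window at both ends; a raw
        day d falls in bin i when ``edges[i] <= d < edges[i+1]``.
    baseline_index
        Position of the pre-flight baseline bin.
    """

    labels: tuple[float, ...] = MISSION_GRID_DAYS
    window: tuple[float, float] = DEFAULT_WINDOW
    baseline_index: int = BASELINE_INDEX
    edges: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=float)
        if labels.ndim != 1 or len(labels) < 2:
            raise ValueError("grid needs at least two bin labels")
        if np.any(np.diff(labels) <= 0):
            raise ValueError("bin labels must be strictly increasing")
        lo, hi = self.window
        if not (lo <= labels[0] and labels[-1] <= hi):
            raise ValueError("window must contain all bin labels")
        if not 0 <= self.baseline_index < len(labels):
            raise ValueError("baseline_index outside the grid")
        mids = (labels[:-1] + labels[1:]) / 2.0
        object.__setattr__(self, "edges", (lo, *mids.tolist(), hi))

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @property
    def baseline_day(self) -> float:
        return self.labels[self.baseline_index]

    def bin_index(self, day: float) -> int | None:
        """Bin index for a raw day, or None when outside the window."""
        edges = np.asarray(self.edges)
        if not (edges[0] <= day < edges[-1]):
            return None
        return int(np.searchsorted(edges, day, side="right") - 1)

    def bin_indices(self, days: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bin_index`; out-of-window days map to -1."""
        days = np.asarray(days, dtype=float)
        edges = np.asarray(self.edges)
        idx = np.searchsorted(edges, days, side="right") - 1
        idx[(days < edges[0]) | (days >= edges[-1])] = -1
        return idx
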