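"""Containers for time-series snapshot data.

A *snapshot* is an unpaired sample of cells measured at one time point:
cells are destroyed by measurement, so no cell appears at two times.  The
model connects the per-time densities, so all a dataset needs is the sample
matrix, the time, and the population mass relative to the first time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Snapshot:
    """Cells-by-features sample at one time point.

    Parameters
    ----------
    time : float
        Measurement time.
    X : ndarray of shape (n_cells, d)
        Expression (or reduced-coordinate) matrix.
    relative_mass : float
        Population size relative to the first snapshot (first snapshot has
        relative mass 1 by construction).
    """

    time: float
    X: np.ndarray
    relative_mass: float = 1.0

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] < 1:
            raise ValueError("snapshot must contain at least one cell")
        if self.relative_mass <= 0:
            raise ValueError("relative_mass must be positive")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class TimeSeriesDataset:
    """An ordered collection of snapshots with consistent dimensionality."""

    snapshots: list[Snapshot] = field(default_factory=list)

    def __post_init__(self):
        times = [s.time for s in self.snapshots]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("snapshot times must be strictly increasing")
        dims = {s.n_features for s in self.snapshots}
        if len(dims) > 1:
            raise ValueError(f"inconsistent feature counts across snapshots: {dims}")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i) -> Snapshot:
        return self.snapshots[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.relative_mass for s in self.snapshots])

    @property
    def n_features(self) -> int:
        return self.snapshots[0].n_features

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, t) with one row per cell, for estimator-style APIs."""
        X = np.vstack([s.X for s in self.snapshots])
        t = np.concatenate([np.full(s.n_cells, s.time) for s in self.snapshots])
        return X, t
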