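"""Gapped scalar time series and contiguous segments.

Per-residue observables (the water order parameter averaged over contact
waters, or the residue RMSD) are stored as uniformly sampled series in which
undefined entries are NaN: a residue may simply have no contact water with a
defined order parameter in a given frame.  Relaxation analysis operates on
the maximal gap-free segments of such a series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GappedSeries:
    """Uniformly sampled scalar series with explicit undefined (NaN) entries."""

    residue: int
    values: np.ndarray
    dt: float  # ps
    quantity: str = "zeta"  # "zeta" | "rmsd"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("series values must be one-dimensional")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined_mask.sum())


@dataclass
class Segment:
    """A maximal gap-free run of a :class:`GappedSeries` (half-open frames)."""

    start: int
    end: int
    values: np.ndarray = field(repr=False)
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.isnan(self.values).any():
            raise ValueError("segment values must contain no undefined entries")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def duration(self) -> float:
        """Segment length in ps."""
        return len(self) * self.dt
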