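"""Core data containers shared by all analysis stages.

All times are in seconds (float64), positions in cm, intervals half-open
``[start, stop)``.  Neurons are identified by non-negative integer ids.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The theta band used throughout: 4-12 Hz, i.e. cycle lengths of 83-250 ms.
THETA_BAND = (4.0, 12.0)
THETA_CYCLE_BOUNDS_S = (1.0 / THETA_BAND[1], 1.0 / THETA_BAND[0])


@dataclass
class SpikeTrainSet:
    """Sorted spike trains for a set of simultaneously recorded neurons.

    Parameters
    ----------
    trains
        Mapping of neuron id to a sorted 1-D array of spike times (s).
    region
        Optional mapping of neuron id to anatomical region (e.g. ``"dCA1"``,
        ``"NAc"``).
    putative_class
        Optional mapping of neuron id to putative cell class
        (``"PYR"``, ``"MSN"``, ``"FSI"``, ``"TAN"``).
    """

    trains: dict[int, np.ndarray]
    region: dict[int, str] = field(default_factory=dict)
    putative_class: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for nid, t in self.trains.items():
            t = np.asarray(t, dtype=float).ravel()
            if t.size and np.any(np.diff(t) < 0):
                t = np.sort(t)
            clean[int(nid)] = t
        self.trains = clean

    @property
    def neuron_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def __getitem__(self, nid: int) -> np.ndarray:
        return self.trains[nid]

    def select(self, ids) -> "SpikeTrainSet":
        ids = [int(i) for i in ids]
        return SpikeTrainSet(
            {i: self.trains[i] for i in ids},
            {i: self.region[i] for i in ids if i in self.region},
            {i: self.putative_class[i] for i in ids if i in self.putative_class},
        )

    def by_class(self, cls: str) -> "SpikeTrainSet":
        return self.select([i for i, c in self.putative_class.items() if c == cls])

    def restrict(self, interval) -> "SpikeTrainSet":
        """Return spikes inside the half-open interval ``[a, b)``."""
        a, b = float(interval[0]), float(interval[1])
        return SpikeTrainSet(
            {i: t[(t >= a) & (t < b)] for i, t in self.trains.items()},
            dict(self.region),
            dict(self.putative_class),
        )

    def rate(self, nid: int, interval) -> float:
        a, b = float(interval[0]), float(interval[1])
        t = self.trains[nid]
        return float(np.count_nonzero((t >= a) & (t < b))) / (b - a)

    def count(self, nid: int, epochs) -> int:
        """Total spike count of one neuron over a list of ``[a, b)`` epochs."""
        t = self.trains[nid]
        n = 0
        for a, b in epochs:
            n += int(np.searchsorted(t, b) - np.searchsorted(t, a))
        return n


@dataclass
class ThetaCycles:
    """Ordered theta-cycle boundaries with a piecewise-linear phase map.

    ``boundaries`` holds the ``n_cycles + 1`` cycle start times (the last
    entry closes the final cycle).  Phase is 0 at each boundary and increases
    linearly to ``2*pi`` at the next one.  Cycles whose length falls outside
    the 4-12 Hz band (83-250 ms) are flagged invalid and are skipped by the
    surrogate and cycle-binning machinery.
    """

    boundaries: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float).ravel()
        if b.size < 2:
            raise ValueError("need at least two boundaries (one cycle)")
        if np.any(np.diff(b) <= 0):
            raise ValueError("cycle boundaries must be strictly increasing")
        self.boundaries = b
        lengths = np.diff(b)
        lo, hi = THETA_CYCLE_BOUNDS_S
        in_band = (lengths >= lo - 1e-12) & (lengths <= hi + 1e-12)
        if self.valid is None:
            self.valid = in_band
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & in_band

    @property
    def n_cycles(self) -> int:
        return self.boundaries.size - 1

    @property
    def cycle_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def valid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.valid)

    @property
    def start(self) -> float:
        return float(self.boundaries[0])

    @property
    def stop(self) -> float:
        return float(self.boundaries[-1])

    def cycle_of(self, times) -> np.ndarray:
        """Cycle index containing each time; -1 outside coverage."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        idx[(t < self.start) | (t >= self.stop)] = -1
        idx[idx == self.n_cycles] = -1
        return idx

    def phase(self, times) -> np.ndarray:
        """Theta phase in ``[0, 2*pi)`` of each time; NaN outside coverage."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = self.cycle_of(t)
        out = np.full(t.shape, np.nan)
        ok = idx >= 0
        b = self.boundaries
        frac = (t[ok] - b[idx[ok]]) / (b[idx[ok] + 1] - b[idx[ok]])
        out[ok] = 2.0 * np.pi * frac
        return out

    def time_at_phase(self, cycle_idx, phase) -> np.ndarray:
        """Invert the phase map: time in cycle ``cycle_idx`` at ``phase``."""
        c = np.asarray(cycle_idx, dtype=int)
        p = np.asarray(phase, dtype=float)
        b = self.boundaries
        return b[c] + (p / (2.0 * np.pi)) * (b[c + 1] - b[c])


@dataclass
class PositionTrace:
    """Animal position samples (nominally 25 Hz camera frames)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size > 1 else 0.0

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.t))) if self.t.size > 1 else 0.0

    def at(self, times) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated position at arbitrary times."""
        times = np.asarray(times, dtype=float)
        return (np.interp(times, self.t, self.x), np.interp(times, self.t, self.y))


def validate_interval(interval) -> tuple[float, float]:
    a, b = float(interval[0]), float(interval[1])
    if not b > a:
        raise ValueError(f"interval [{a}, {b}) is empty")
    return a, b
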