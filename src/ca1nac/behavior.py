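"""Behavioral scoring of place-preference sessions and spatial occupancy.

The conditioned place-preference (CPP) score is the normalized dwell-time
difference between the reward-paired and the other enclosure,

    score = (t_target - t_other) / (t_target + t_other),

with time on the connecting bridge excluded from the denominator.  The
same formula serves the novel-place-preference (NPP) score with the novel
enclosure as target.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

from .core import PositionTrace


@dataclass
class EnclosureGeometry:
    """Polygonal masks (cm) for two enclosures and the connecting bridge."""

    box_a: Polygon
    box_b: Polygon
    bridge: Polygon

    def __post_init__(self):
        if self.box_a.intersects(self.box_b) and self.box_a.intersection(
            self.box_b
        ).area > 0:
            raise ValueError("enclosure masks must be disjoint")

    @classmethod
    def two_box_bridge(cls) -> "EnclosureGeometry":
        """The standard apparatus: two 46 x 46 cm square enclosures joined
        by an 8-cm-long, 7-cm-wide bridge."""
        a = Polygon([(0, 0), (46, 0), (46, 46), (0, 46)])
        b = Polygon([(54, 0), (100, 0), (100, 46), (54, 46)])
        bridge = Polygon([(46, 19.5), (54, 19.5), (54, 26.5), (46, 26.5)])
        return cls(a, b, bridge)

    @property
    def box_a_bounds(self):
        x0, y0, x1, y1 = self.box_a.bounds
        return (x0, x1, y0, y1)

    @property
    def box_b_bounds(self):
        x0, y0, x1, y1 = self.box_b.bounds
        return (x0, x1, y0, y1)

    def label(self, x, y) -> np.ndarray:
        """Per-sample enclosure label: ``A``, ``B``, ``bridge`` or ``other``."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        out = np.full(x.shape, "other", dtype=object)
        # tiny buffer so samples exactly on a wall still count as inside
        eps = 1e-9
        out[contains_xy(self.box_a.buffer(eps), x, y)] = "A"
        out[contains_xy(self.box_b.buffer(eps), x, y)] = "B"
        out[contains_xy(self.bridge.buffer(eps), x, y)] = "bridge"
        return out


def dwell_times(trace: PositionTrace, geometry: EnclosureGeometry) -> dict:
    """Seconds spent in each region, one frame interval per sample."""
    if trace.n_samples == 0:
        return {"A": 0.0, "B": 0.0, "bridge": 0.0, "other": 0.0}
    dt = np.empty(trace.n_samples)
    if trace.n_samples > 1:
        dt[:-1] = np.diff(trace.t)
        dt[-1] = dt[-2] if trace.n_samples > 2 else dt[0]
    else:
        dt[:] = 0.0
    labels = geometry.label(trace.x, trace.y)
    return {
        region: float(dt[labels == region].sum())
        for region in ("A", "B", "bridge", "other")
    }


def preference_score(
    trace: PositionTrace, geometry: EnclosureGeometry, pairing: str = "A"
) -> float:
    """Normalized dwell difference in [-1, 1]; ``pairing`` names the
    sucrose-paired (or novel) target enclosure, ``"A"`` or ``"B"``.

    Raises
    ------
    ValueError if total enclosure dwell time is zero (score undefined).
    """
    if pairing not in ("A", "B"):
        raise ValueError("pairing must be 'A' or 'B'")
    d = dwell_times(trace, geometry)
    target = d[pairing]
    other = d["B" if pairing == "A" else "A"]
    total = target + other
    if total <= 0:
        raise ValueError("zero total enclosure dwell time: score undefined")
    return float((target - other) / total)


def occupancy_map(trace: PositionTrace, spatial_bin_cm: float = 2.0):
    """2-D dwell-time map (seconds per spatial bin).

    Returns ``(H, x_edges, y_edges)``; ``H.sum()`` equals the trace
    duration to within one frame interval.
    """
    if trace.n_samples == 0:
        raise ValueError("empty position trace")
    dt = np.empty(trace.n_samples)
    if trace.n_samples > 1:
        dt[:-1] = np.diff(trace.t)
        dt[-1] = dt[-2] if trace.n_samples > 2 else dt[0]
    else:
        dt[:] = 1.0
    def _edges(v):
        lo = np.floor(v.min())
        hi = max(np.ceil(v.max()), lo + spatial_bin_cm)
        return np.arange(lo, hi + spatial_bin_cm, spatial_bin_cm)

    x_edges = _edges(trace.x)
    y_edges = _edges(trace.y)
    H, xe, ye = np.histogram2d(
        trace.x, trace.y, bins=(x_edges, y_edges), weights=dt
    )
    return H, xe, ye


def count_events_by_region(
    event_x, event_y, geometry: EnclosureGeometry
) -> dict:
    """Per-region counts of point events (e.g. pokes at reward containers)."""
    x = np.atleast_1d(np.asarray(event_x, float))
    y = np.atleast_1d(np.asarray(event_y, float))
    if x.size == 0:
        return {"A": 0, "B": 0, "bridge": 0, "other": 0, "total": 0}
    labels = geometry.label(x, y)
    out = {
        region: int(np.count_nonzero(labels == region))
        for region in ("A", "B", "bridge", "other")
    }
    out["total"] = int(x.size)
    return out


def interpolate_dropouts(trace: PositionTrace, max_gap_s: float = 0.5) -> PositionTrace:
    """Fill missing tracking frames (NaN x/y) by linear interpolation for
    gaps up to ``max_gap_s``; longer gaps are dropped."""
    bad = ~(np.isfinite(trace.x) & np.isfinite(trace.y))
    if not bad.any():
        return trace
    t, x, y = trace.t.copy(), trace.x.copy(), trace.y.copy()
    good = ~bad
    if good.sum() < 2:
        raise ValueError("not enough valid samples to interpolate")
    x[bad] = np.interp(t[bad], t[good], x[good])
    y[bad] = np.interp(t[bad], t[good], y[good])
    # drop samples inside gaps longer than max_gap_s
    keep = np.ones(t.size, bool)
    gid = np.flatnonzero(bad)
    if gid.size:
        splits = np.split(gid, np.flatnonzero(np.diff(gid) > 1) + 1)
        for run in splits:
            lo = t[run[0] - 1] if run[0] > 0 else t[run[0]]
            hi = t[run[-1] + 1] if run[-1] + 1 < t.size else t[run[-1]]
            if hi - lo > max_gap_s:
                keep[run] = False
    return PositionTrace(t[keep], x[keep], y[keep])
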