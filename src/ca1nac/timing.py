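"""Cross-region spike-timing analysis under theta-oscillation control.

Cross-correlograms give the discharge probability of a target neuron
around reference (PYR) spikes.  To separate genuine short-latency
(monosynaptic) interactions from mere theta co-modulation, surrogate
reference trains are built by relocating every spike to a random theta
cycle at its original theta phase: the phase histogram is preserved
exactly while fine timing is destroyed.  The original correlogram is then
compared against per-bin quantile bands over (by default) 1000 surrogates.

Also here: light-driven firing-rate scores, kernel density of score
populations, theta-modulation depth (Rayleigh vector length) and the
kinetics of average postsynaptic potentials from slice recordings.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert
from scipy.stats import gaussian_kde

from .core import THETA_BAND, ThetaCycles

DEFAULT_CCG_WINDOW_S = 0.2
DEFAULT_CCG_BIN_S = 0.001
DEFAULT_N_SURROGATES = 1000
DEFAULT_BAND_QUANTILES = (0.005, 0.995)


# --------------------------------------------------------------------------
# theta cycles
# --------------------------------------------------------------------------


def detect_theta_cycles(
    series,
    fs_hz: float,
    band=THETA_BAND,
    is_phase: bool = False,
) -> ThetaCycles:
    """Segment a signal into theta cycles.

    If ``is_phase`` the series is taken as instantaneous phase (rad) and
    boundaries are placed at its (interpolated) zero crossings.  Otherwise
    the signal is band-pass filtered (Butterworth, zero-phase) in ``band``
    and the phase taken from the analytic signal.  Cycles outside the
    83-250 ms band are flagged invalid and excluded downstream.
    """
    x = np.asarray(series, float).ravel()
    if x.size < fs_hz / band[0]:
        raise ValueError("series shorter than one theta cycle")
    t = np.arange(x.size) / fs_hz
    if is_phase:
        phase = np.unwrap(x)
    else:
        nyq = fs_hz / 2.0
        b, a = butter(3, [band[0] / nyq, band[1] / nyq], btype="band")
        # mirror-pad by ~2 slow cycles to keep filter/hilbert edge
        # transients away from the analyzed span
        pad = min(x.size - 1, int(2 * fs_hz / band[0]))
        xp = np.concatenate(
            [2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2 : -pad - 2 : -1]]
        )
        filtered = filtfilt(b, a, xp)
        phase = np.unwrap(np.angle(hilbert(filtered)))[pad : pad + x.size]
    # boundary wherever unwrapped phase crosses a multiple of 2*pi
    k0 = np.ceil(phase[0] / (2 * np.pi))
    k1 = np.floor(phase[-1] / (2 * np.pi))
    targets = 2 * np.pi * np.arange(k0, k1 + 1)
    if targets.size < 2:
        raise ValueError("series contains less than one full cycle")
    boundaries = np.interp(targets, phase, t)
    return ThetaCycles(boundaries)


# --------------------------------------------------------------------------
# cross-correlograms
# --------------------------------------------------------------------------


@dataclass
class Correlogram:
    """Discharge probability of a target train around reference spikes."""

    lag_centers_s: np.ndarray
    probability: np.ndarray
    n_reference_spikes: int
    band_low: np.ndarray = None
    band_high: np.ndarray = None
    surrogate_prob: np.ndarray = None  # (n_surrogates, n_bins), when kept
    band_level: float = DEFAULT_BAND_QUANTILES[1]

    @property
    def lag_centers_ms(self) -> np.ndarray:
        return self.lag_centers_s * 1e3

    def exceeds_band(self, lag_range_ms) -> bool:
        """True if the correlogram significantly exceeds the surrogate
        band somewhere within the lag range (ms).

        A claim over a *window* of bins needs a simultaneous threshold:
        when the surrogate correlograms are available, the original's
        maximum over the window bins is compared against the same upper
        quantile of the per-surrogate maxima (exact family-wise level by
        construction).  Without them, the per-bin upper band is used,
        whose family-wise rate grows with the window width.
        """
        lo, hi = lag_range_ms
        m = (self.lag_centers_ms >= lo) & (self.lag_centers_ms <= hi)
        if self.surrogate_prob is not None:
            thr = np.quantile(self.surrogate_prob[:, m].max(axis=1), self.band_level)
            return bool(self.probability[m].max() > thr)
        if self.band_high is None:
            raise ValueError("no surrogate band attached")
        return bool(np.any(self.probability[m] > self.band_high[m]))


def _ccg_counts(reference, target, edges):
    """Target-spike count per lag bin, pooled over reference spikes."""
    n_bins = edges.size - 1
    lo, hi = edges[0], edges[-1]
    bin_w = edges[1] - edges[0]
    i0 = np.searchsorted(target, reference + lo, side="left")
    i1 = np.searchsorted(target, reference + hi, side="right")
    lengths = i1 - i0
    total = int(lengths.sum())
    if total == 0:
        return np.zeros(n_bins)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    flat = np.arange(total) - starts.repeat(lengths) + i0.repeat(lengths)
    lags = target[flat] - reference.repeat(lengths)
    bins = np.floor((lags - lo) / bin_w).astype(int)
    ok = (bins >= 0) & (bins < n_bins)
    return np.bincount(bins[ok], minlength=n_bins).astype(float)


def cross_correlogram(
    reference,
    target,
    window_s: float = DEFAULT_CCG_WINDOW_S,
    bin_s: float = DEFAULT_CCG_BIN_S,
) -> Correlogram:
    """Discharge probability of ``target`` around ``reference`` spikes.

    For each reference spike, target spikes are binned by lag over
    ``+-window_s``; counts are normalized by the number of reference
    spikes, giving spikes per reference spike per bin.
    """
    reference = np.sort(np.asarray(reference, float))
    target = np.sort(np.asarray(target, float))
    if reference.size == 0 or target.size == 0:
        raise ValueError("both spike trains must be non-empty")
    n_bins = int(round(2 * window_s / bin_s))
    edges = -window_s + bin_s * np.arange(n_bins + 1)
    counts = _ccg_counts(reference, target, edges)
    return Correlogram(
        lag_centers_s=(edges[:-1] + edges[1:]) / 2.0,
        probability=counts / reference.size,
        n_reference_spikes=int(reference.size),
    )


def theta_shift_surrogates(
    reference,
    target,
    cycles: ThetaCycles,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
    window_s: float = DEFAULT_CCG_WINDOW_S,
    bin_s: float = DEFAULT_CCG_BIN_S,
    quantiles=DEFAULT_BAND_QUANTILES,
    return_trains: bool = False,
):
    """Theta-phase-preserving shift surrogates and their correlogram band.

    Every reference spike is relocated, independently per spike and per
    surrogate, to a uniformly random valid theta cycle at the time whose
    phase equals the spike's original phase (phase-to-time by the cycle's
    linear phase map).  Spike count and phase multiset are preserved
    exactly.  Reference spikes outside the covered cycles are excluded
    (with a warning).  Returns the original correlogram with the per-bin
    quantile band attached, plus the surrogate trains if requested.
    """
    import warnings as _warnings

    reference = np.sort(np.asarray(reference, float))
    target = np.sort(np.asarray(target, float))
    cyc_idx = cycles.cycle_of(reference)
    inside = (cyc_idx >= 0) & cycles.valid[np.clip(cyc_idx, 0, None)]
    if not inside.all():
        _warnings.warn(
            f"{int((~inside).sum())} reference spikes outside covered theta "
            "cycles were excluded",
            stacklevel=2,
        )
    reference = reference[inside]
    if reference.size == 0:
        raise ValueError("no reference spikes inside covered theta cycles")
    phases = cycles.phase(reference)

    valid_cycles = cycles.valid_indices
    rng = np.random.default_rng(seed)
    n_bins = int(round(2 * window_s / bin_s))
    edges = -window_s + bin_s * np.arange(n_bins + 1)

    ccg = cross_correlogram(reference, target, window_s, bin_s)
    surr_prob = np.empty((n_surrogates, n_bins))
    trains = [] if return_trains else None
    for s in range(n_surrogates):
        pick = valid_cycles[rng.integers(0, valid_cycles.size, reference.size)]
        shifted = np.sort(cycles.time_at_phase(pick, phases))
        surr_prob[s] = _ccg_counts(shifted, target, edges) / shifted.size
        if return_trains:
            trains.append(shifted)
    ccg.band_low = np.quantile(surr_prob, quantiles[0], axis=0)
    ccg.band_high = np.quantile(surr_prob, quantiles[1], axis=0)
    ccg.surrogate_prob = surr_prob
    ccg.band_level = quantiles[1]
    if return_trains:
        return ccg, trains
    return ccg


# --------------------------------------------------------------------------
# rate scores and densities
# --------------------------------------------------------------------------


def _epoch_rate(spikes, epochs) -> float:
    spikes = np.asarray(spikes, float)
    total_t = sum(b - a for a, b in epochs)
    if total_t <= 0:
        raise ValueError("epochs have zero total duration")
    n = sum(
        int(np.searchsorted(spikes, b) - np.searchsorted(spikes, a))
        for a, b in epochs
    )
    return n / total_t


def light_rate_score(spikes, on_epochs, off_epochs) -> float:
    """Light-driven firing-rate score: (r_ON - r_OFF) / (r_ON + r_OFF).

    Antisymmetric under ON/OFF exchange; the same function applied to the
    two flanking OFF epochs gives the control score.  Returns NaN when
    both rates are zero (unit excluded, undefined score).
    """
    if not on_epochs or not off_epochs:
        raise ValueError("both epoch sets must be non-empty")
    r_on = _epoch_rate(spikes, on_epochs)
    r_off = _epoch_rate(spikes, off_epochs)
    if r_on + r_off == 0:
        return float("nan")
    return float((r_on - r_off) / (r_on + r_off))


def score_density(
    scores,
    bandwidth: float = None,
    grid=None,
):
    """Gaussian kernel density of a score population on [-1, 1].

    Bandwidth defaults to Silverman's rule clipped to [0.02, 0.2] on the
    score scale.  Returns ``(grid, density)`` with the density integrating
    to ~1 over the evaluation grid.
    """
    scores = np.asarray(scores, float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise ValueError("need at least two finite scores")
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 401)
    sd = scores.std(ddof=1)
    if bandwidth is None:
        silverman = 1.06 * sd * scores.size ** (-1 / 5) if sd > 0 else 0.02
        bandwidth = float(np.clip(silverman, 0.02, 0.2))
    # gaussian_kde's factor multiplies the data SD; handle sd=0 directly
    if sd == 0:
        dens = np.exp(-0.5 * ((grid - scores[0]) / bandwidth) ** 2) / (
            bandwidth * np.sqrt(2 * np.pi)
        )
    else:
        kde = gaussian_kde(scores, bw_method=bandwidth / sd)
        dens = kde(grid)
    dens = dens / np.trapezoid(dens, grid)
    return grid, dens


def theta_modulation_depth(spikes, phase_of) -> float:
    """Rayleigh vector length of spike theta phases, in [0, 1].

    ``phase_of`` is either a callable mapping times to phases (rad) or a
    precomputed array of spike phases.  Spikes with undefined (NaN) phase
    are ignored; at least one spike must fall inside phase coverage.
    """
    spikes = np.asarray(spikes, float)
    phases = np.asarray(phase_of(spikes) if callable(phase_of) else phase_of, float)
    phases = phases[np.isfinite(phases)]
    if phases.size == 0:
        raise ValueError("no spikes inside phase coverage")
    return float(np.abs(np.exp(1j * phases).mean()))


# --------------------------------------------------------------------------
# slice PSP kinetics
# --------------------------------------------------------------------------


@dataclass
class PSPKinetics:
    """Kinetics of an average postsynaptic potential."""

    amplitude: float
    duration_s: float
    rise_time_s: float  # 20-80% of peak amplitude
    paired_pulse_ratio: float = None
    event_found: bool = True


def _crossing_time(t, y, level, i_from, i_to):
    """First linear-interpolated crossing of ``level`` in t[i_from:i_to]."""
    for i in range(i_from, i_to):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return t[i] + (level - y0) * (t[i + 1] - t[i]) / (y1 - y0)
    return None


def _event_kinetics(t, y, mu, sd, min_event_s: float = 0.001):
    """Amplitude / duration / rise time of the first supra-2-SD event.

    An event must stay above threshold for at least ``min_event_s`` so
    isolated noise samples crossing 2 SD do not count.
    """
    thr = mu + 2.0 * sd
    above = y > thr
    if not above.any():
        return None
    dt = t[1] - t[0] if t.size > 1 else min_event_s
    min_run = max(1, int(round(min_event_s / dt)))
    # first run of >= min_run consecutive supra-threshold samples
    i_start = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            i_start = i - run + 1
            break
    if i_start is None:
        return None
    # event end: first return below threshold after the peak
    seg_end = i_start
    while seg_end < y.size and y[seg_end] > thr:
        seg_end += 1
    i_peak = i_start + int(np.argmax(y[i_start:seg_end] if seg_end > i_start else y[i_start:]))
    amp = float(y[i_peak] - mu)
    t20 = _crossing_time(t, y, mu + 0.2 * amp, max(i_start - 1, 0), i_peak)
    t80 = _crossing_time(t, y, mu + 0.8 * amp, max(i_start - 1, 0), i_peak)
    rise = (t80 - t20) if (t20 is not None and t80 is not None) else np.nan
    duration = float(t[min(seg_end, t.size - 1)] - t[i_start])
    return amp, duration, rise, i_peak, seg_end


def psp_kinetics(
    trace,
    fs_hz: float,
    baseline_window_s,
    n_pulses: int = 1,
) -> PSPKinetics:
    """Kinetics of an average PSP trace.

    The baseline mean and SD are computed on ``baseline_window_s`` (which
    must precede the stimulus); events are upward deflections of more than
    2 baseline SDs.  The peak amplitude is measured relative to baseline,
    and the rise time is the 20%-to-80%-of-peak interval (linear
    interpolation).  With ``n_pulses = 2`` the paired-pulse ratio (second
    amplitude / first amplitude) is also returned.  If no supra-threshold
    deflection exists the result is flagged ``event_found = False``.
    """
    y = np.asarray(trace, float).ravel()
    t = np.arange(y.size) / fs_hz
    b0, b1 = baseline_window_s
    base = y[(t >= b0) & (t < b1)]
    if base.size < 2:
        raise ValueError("baseline window contains too few samples")
    mu, sd = float(base.mean()), float(base.std())
    after = t >= b1
    t_a, y_a = t[after], y[after]
    first = _event_kinetics(t_a, y_a, mu, sd)
    if first is None:
        return PSPKinetics(0.0, 0.0, np.nan, None, event_found=False)
    amp, duration, rise, i_peak, seg_end = first
    ppr = None
    if n_pulses == 2:
        second = _event_kinetics(t_a[seg_end:], y_a[seg_end:], mu, sd)
        if second is not None and amp != 0:
            ppr = float(second[0] / amp)
    return PSPKinetics(amp, duration, rise, ppr)
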